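"""End-to-end workflow: profile a set of candidate screening libraries and
rank them by two-level dense-rank consensus.

Per library the workflow emits a curation report, an ADME/T report (percent
failing Lipinski, failing Veber, predicted logBB < 0), a promiscuous-binder
report, and an internal-diversity report (mean pairwise Tanimoto for each
configured diversity fingerprint).  Optionally it adds similarity-to-active
counts (fingerprint threshold searches plus a substructure query) and
overlap with an in-house collection at a Tanimoto cutoff.  Available blocks
feed the consensus; a missing optional input skips its block (logged) and
the rest proceeds.  Library size is reported but never ranked.

Reports are plain CSVs; a re-run with the same configuration and seed
produces byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import admet, alerts, consensus, curation, divsim
from .chemio import Library, LibrankError, read_library, records_from_smiles, write_report

logger = logging.getLogger("librank")

DEFAULT_DIVERSITY_DIALECTS = ["ECFP_2", "MDL_keys", "PHRFC_2"]
DEFAULT_SIMILARITY_DIALECTS = ["ECFP_4", "ECFP_6", "MDL_keys", "PHFP_3"]


@dataclass
class WorkflowConfig:
    libraries: list[dict] = field(default_factory=list)  # {name, path}
    reference_actives: list[str] = field(default_factory=list)
    in_house: str | None = None
    alert_catalog: str | None = None
    diversity_dialects: list[str] = field(default_factory=lambda: list(DEFAULT_DIVERSITY_DIALECTS))
    similarity_dialects: list[str] = field(default_factory=lambda: list(DEFAULT_SIMILARITY_DIALECTS))
    substructure_query: dict | None = None  # {template, elements}
    similarity_threshold: float = 0.7
    overlap_threshold: float = 0.7
    max_pairs: int = 20000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise LibrankError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class WorkflowResult:
    curation: pd.DataFrame
    admet: pd.DataFrame
    alerts: pd.DataFrame
    diversity: pd.DataFrame
    similarity: pd.DataFrame | None
    overlap: pd.DataFrame | None
    consensus: pd.DataFrame
    best_library: str
    sizes: dict[str, int]

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "curation": self.curation,
            "admet": self.admet,
            "alerts": self.alerts,
            "diversity": self.diversity,
            "consensus": self.consensus,
        }
        if self.similarity is not None:
            out["similarity"] = self.similarity
        if self.overlap is not None:
            out["overlap"] = self.overlap
        return out


def _load_libraries(config: WorkflowConfig) -> list[Library]:
    libs = []
    for entry in config.libraries:
        libs.append(read_library(entry["path"], name=entry.get("name")))
    return libs


def run_workflow(
    config: WorkflowConfig,
    libraries: list[Library] | None = None,
    out_dir: str | Path | None = None,
) -> WorkflowResult:
    """Run the full pipeline; see the module docstring.

    ``libraries`` may be passed directly (e.g. synthetic fixtures); otherwise
    they are read from the paths in the configuration.
    """
    libs = libraries if libraries is not None else _load_libraries(config)
    if not libs:
        raise LibrankError("no libraries to analyze")
    if len({l.name for l in libs}) != len(libs):
        raise LibrankError("library names must be unique")

    catalog = alerts.load_catalog(config.alert_catalog) if config.alert_catalog else alerts.default_catalog()

    curated: dict[str, Library] = {}
    cur_rows, admet_rows, alert_rows, div_rows = [], [], [], []
    sizes: dict[str, int] = {}
    for lib in libs:
        cur, report = curation.curate(lib)
        curated[lib.name] = cur
        sizes[lib.name] = len(cur)
        cur_rows.append(report.to_frame())
        admet_rows.append(admet.admet_report(cur))
        alert_rows.append(alerts.alert_report(cur, catalog))
        row = {"library": lib.name}
        for dialect in config.diversity_dialects:
            ms = divsim.mean_pairwise_similarity(
                cur.records, dialect, max_pairs=config.max_pairs, seed=config.seed
            )
            row[f"mean_similarity_{dialect}"] = round(ms.value, 6)
        div_rows.append(pd.DataFrame([row]))

    curation_df = pd.concat(cur_rows, ignore_index=True)
    admet_df = pd.concat(admet_rows, ignore_index=True)
    alerts_df = pd.concat(alert_rows, ignore_index=True)
    diversity_df = pd.concat(div_rows, ignore_index=True)

    # --- consensus blocks -------------------------------------------------
    def column_table(df: pd.DataFrame, col: str, direction: str) -> consensus.CriterionTable:
        return consensus.CriterionTable(
            name=col,
            values=dict(zip(df["library"], df[col].astype(float))),
            direction=direction,
        )

    admet_block = consensus.block_consensus(
        [
            column_table(admet_df, "fail_lipinski_pct", consensus.LOWER_BETTER),
            column_table(admet_df, "fail_veber_pct", consensus.LOWER_BETTER),
            column_table(admet_df, "logbb_below_zero_pct", consensus.LOWER_BETTER),
        ]
    )
    promiscuity_block = consensus.block_consensus(
        [column_table(alerts_df, "promiscuous_pct", consensus.LOWER_BETTER)]
    )
    diversity_block = consensus.block_consensus(
        [
            column_table(diversity_df, f"mean_similarity_{d}", consensus.LOWER_BETTER)
            for d in config.diversity_dialects
        ]
    )
    blocks = {
        "admet": admet_block.block_ranks,
        "promiscuity": promiscuity_block.block_ranks,
        "diversity": diversity_block.block_ranks,
    }

    # --- optional similarity-to-actives block -----------------------------
    similarity_df = None
    if config.reference_actives:
        refs = records_from_smiles(config.reference_actives, source="reference")
        sim_rows = []
        for lib_name, cur in curated.items():
            row = {"library": lib_name}
            for dialect in config.similarity_dialects:
                hits: set[int] = set()
                for ref in refs:
                    hits.update(
                        divsim.threshold_search(cur.records, ref, dialect, config.similarity_threshold)
                    )
                row[f"similar_count_{dialect}"] = len(hits)
            if config.substructure_query:
                query = divsim.SubstructureQuery.from_template(
                    config.substructure_query["template"],
                    config.substructure_query.get("elements", []),
                )
                row["substructure_count"] = len(divsim.substructure_search(cur.records, query))
            sim_rows.append(pd.DataFrame([row]))
        similarity_df = pd.concat(sim_rows, ignore_index=True)
        sim_tables = [
            column_table(similarity_df, c, consensus.HIGHER_BETTER)
            for c in similarity_df.columns
            if c != "library"
        ]
        blocks["similarity"] = consensus.block_consensus(sim_tables).block_ranks
    else:
        logger.info("no reference actives configured; similarity block skipped")

    totals, final = consensus.total_consensus(list(blocks.values()))

    # --- optional in-house overlap ----------------------------------------
    overlap_df = None
    if config.in_house:
        in_house = read_library(config.in_house, name="in_house")
        in_house_cur, _ = curation.curate(in_house)
        rows = []
        for lib_name, cur in curated.items():
            count, pct = divsim.compare_libraries(
                cur, in_house_cur, dialect="ECFP_4", threshold=config.overlap_threshold
            )
            rows.append({"library": lib_name, "overlap_count": count, "overlap_pct": pct})
        overlap_df = pd.DataFrame(rows)
        overlap_table = consensus.CriterionTable(
            name="overlap_pct",
            values=dict(zip(overlap_df["library"], overlap_df["overlap_pct"].astype(float))),
            direction=consensus.LOWER_BETTER,
        )
        combined, final = consensus.overlap_adjusted_rank(final, overlap_table)
        totals = combined
    else:
        logger.info("no in-house library configured; overlap block skipped")

    lib_names = [l.name for l in libs]
    consensus_df = pd.DataFrame(
        {
            "library": lib_names,
            "size": [sizes[l] for l in lib_names],
            **{f"{b}_rank": [ranks[l] for l in lib_names] for b, ranks in blocks.items()},
            "total_rank": [totals[l] for l in lib_names],
            "final_rank": [final[l] for l in lib_names],
        }
    )
    best = min(lib_names, key=lambda l: (final[l], lib_names.index(l)))

    result = WorkflowResult(
        curation=curation_df,
        admet=admet_df,
        alerts=alerts_df,
        diversity=diversity_df,
        similarity=similarity_df,
        overlap=overlap_df,
        consensus=consensus_df,
        best_library=best,
        sizes=sizes,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in result.tables().items():
            write_report(df, out_dir / f"{name}.csv")
        summary = [
            f"libraries analyzed: {', '.join(lib_names)}",
            f"seed: {config.seed}",
            f"best library: {best} (final rank {final[best]})",
        ]
        (out_dir / "summary.txt").write_text("\n".join(summary) + "\n")
    return result
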