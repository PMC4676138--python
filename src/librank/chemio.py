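"""Chemical file I/O, molecule records and synthetic fixture libraries.

Libraries arrive as SDF (V2000) or SMILES files, one molecule per entry.
Parsing is tolerant: records that cannot be parsed are counted and logged,
never fatal, because vendor files routinely contain occasional junk and the
curation stage reports removals as a statistic.

The fixture generator builds small synthetic libraries with planted
salts, duplicates, inorganics, mixtures and alert-matching compounds so the
whole workflow is testable without any external download.  Generation is a
pure function of (spec, seed).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

logger = logging.getLogger("librank")

# RDKit's C++ logging is noisy on intentionally malformed fixture input.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

DATA_DIR = Path(__file__).resolve().parent / "data"


class LibrankError(Exception):
    """Base class for data/usage errors surfaced by this package."""


class FileFormatError(LibrankError):
    pass


# ---------------------------------------------------------------------------
# records and libraries
# ---------------------------------------------------------------------------

# Sanitization with the valence check disabled: bad-valence structures must
# survive parsing so curation can count them as their own category.
_SANITIZE_NO_VALENCE = Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES


@dataclass
class MoleculeRecord:
    """One library compound: identifier, molecular graph and canonical key."""

    record_id: str
    source: str
    mol: Chem.Mol
    smiles: str = ""
    canonical_key: str = ""
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.smiles:
            self.smiles = Chem.MolToSmiles(self.mol)
        if not self.canonical_key:
            self.canonical_key = Chem.MolToSmiles(self.mol)

    def with_mol(self, mol: Chem.Mol, **extra_flags) -> "MoleculeRecord":
        flags = dict(self.flags)
        flags.update(extra_flags)
        return MoleculeRecord(
            record_id=self.record_id,
            source=self.source,
            mol=mol,
            smiles=Chem.MolToSmiles(mol),
            canonical_key=Chem.MolToSmiles(mol),
            flags=flags,
        )


@dataclass
class Library:
    """Named, ordered collection of molecule records."""

    name: str
    records: list[MoleculeRecord]
    provenance: str = ""
    parse_failures: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise LibrankError("library name must be non-empty")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def mol_from_smiles(smiles: str) -> tuple[Chem.Mol | None, bool]:
    """Parse SMILES leniently.

    Returns (mol, valence_ok).  mol is None when the line is unparseable even
    with the valence check disabled; valence_ok is False for structures that
    only fail the standard valence model (kept, flagged for curation).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is not None:
        return mol, True
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        return None, True
    try:
        Chem.SanitizeMol(mol, _SANITIZE_NO_VALENCE)
    except Exception:
        return None, True
    return mol, False


def _record_from_mol(mol: Chem.Mol, valence_ok: bool, record_id: str, source: str) -> MoleculeRecord:
    flags = {} if valence_ok else {"bad_valence": True}
    return MoleculeRecord(record_id=record_id, source=source, mol=mol, flags=flags)


def read_library(path: str | Path, format: str | None = None, name: str | None = None) -> Library:
    """Read a library from an SDF or SMILES file.

    Unparseable entries are counted on ``Library.parse_failures`` and logged;
    a file with zero parseable records is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"no such file: {path}")
    if format is None:
        format = "sdf" if path.suffix.lower() in {".sdf", ".sd", ".mol"} else "smiles"
    name = name or path.stem

    records: list[MoleculeRecord] = []
    failures = 0
    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False)
        for i, raw in enumerate(supplier):
            if raw is None:
                failures += 1
                logger.warning("%s: SDF entry %d unparseable", path.name, i)
                continue
            rid = raw.GetProp("_Name") if raw.HasProp("_Name") and raw.GetProp("_Name") else f"{name}-{i}"
            valence_ok = True
            try:
                Chem.SanitizeMol(raw)
            except Exception:
                raw2 = None
                try:
                    Chem.SanitizeMol(raw, _SANITIZE_NO_VALENCE)
                    raw2 = raw
                except Exception:
                    pass
                if raw2 is None:
                    failures += 1
                    logger.warning("%s: SDF entry %d unparseable", path.name, i)
                    continue
                valence_ok = False
            records.append(_record_from_mol(raw, valence_ok, rid, name))
    elif format == "smiles":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                rid = parts[1].strip() if len(parts) > 1 else f"{name}-{i}"
                mol, valence_ok = mol_from_smiles(smiles)
                if mol is None:
                    failures += 1
                    logger.warning("%s: line %d unparseable: %r", path.name, i + 1, smiles)
                    continue
                records.append(_record_from_mol(mol, valence_ok, rid, name))
    else:
        raise FileFormatError(f"unknown format: {format!r}")

    if not records:
        raise FileFormatError(f"no parseable records in {path}")
    return Library(name=name, records=records, provenance=str(path), parse_failures=failures)


def write_library(library: Library, path: str | Path, format: str | None = None) -> None:
    """Write a library as a SMILES file (smiles<TAB>id) or SDF."""
    path = Path(path)
    if format is None:
        format = "sdf" if path.suffix.lower() in {".sdf", ".sd"} else "smiles"
    if format == "smiles":
        with open(path, "w") as fh:
            for rec in library.records:
                fh.write(f"{rec.smiles}\t{rec.record_id}\n")
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        for rec in library.records:
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.record_id)
            writer.write(mol)
        writer.close()
    else:
        raise FileFormatError(f"unknown format: {format!r}")


def write_report(table: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write a tabular report as CSV.

    Numeric cells round-trip at full precision (Python repr formatting).
    """
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(list(table))
    if df.columns.duplicated().any():
        raise LibrankError("report column names must be unique")
    df.to_csv(path, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: the default fast parser can be one ulp off
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# synthetic fixture libraries
# ---------------------------------------------------------------------------

# Drug-like enumeration vocabulary for "clean" molecules.  Scaffolds carry
# two substitution points written as {a}/{b}.  Substituents are chosen to be
# inert under the default alert catalog (no catechols, quinones, enones,
# alkyl halides, ...) and under the pKa rules except where noted.
_SCAFFOLDS = [
    "c1ccc({a})cc1{b}",
    "c1ccc2[nH]c({a})cc2c1",
    "c1cnc({a})cc1{b}",
    "c1ccc2nc({a})ccc2c1",
    "C1CCN({a})CC1",
    "c1ccc(-c2ncco2)cc1{a}",
    "c1csc({a})c1{b}",
    "O=C(N{a})c1ccccc1{b}",
    "c1ccc2c(c1)OCC2{a}",
    "c1ccc(N2CCOCC2)c({a})c1",
]

_SUBSTITUENTS = ["C", "CC", "CCC", "OC", "C(C)C", "C(F)(F)F", "F", "C#N", "OCC", "CO"]

# Planted categories (small, hand-picked so ground truth is unambiguous).
_INORGANICS = ["[Fe]", "O", "[Mg+2]", "S=[Se]=S", "[Cu+2]"]
_MIXTURES = [
    "CCO.OCC",
    "c1ccccc1CCO.c1ccncc1CCO",
    "CCCCCCN.CCCCCCO",
    "c1ccc(CCO)cc1.c1ccc(CCN)cc1",
]
_ALERT_HITS = [
    "Oc1ccccc1O",                      # catechol
    "O=C1C=CC(=O)C=C1",                # para-quinone
    "S=C1NC(=O)CS1",                   # rhodanine
    "O=C(/C=C/c1ccccc1)c1ccccc1",      # chalcone (Michael acceptor)
    "BrCCCCc1ccccc1",                  # alkyl halide
    "Cc1ccc([N+](=O)[O-])cc1",         # nitroaromatic
]
# Large, mutually dissimilar scaffolds for labeled analogue clusters: with
# circular fingerprints, within-cluster similarity stays above any
# cross-cluster similarity, so the clusters are well separated by design.
_CLUSTER_SCAFFOLDS = [
    "CC(=O)Nc1ccc(S(=O)(=O)N2CCOCC2)cc1{a}",
    "O=C(c1ccc2[nH]ccc2c1)N1CCN(C)CC1{a}",
    "COc1ccc(-c2nc3ccccc3s2)cc1{a}",
    "O=C1CCc2cc(OCCN3CCCC3)ccc2N1{a}",
    "Cc1ccc(C(=O)Nc2ccccn2)c(S(C)(=O)=O)c1{a}",
    "O=c1[nH]c2ccccc2n1CC(=O)N1CCCCC1{a}",
    "Fc1ccc(C2CC(c3ccon3)=NN2C(C)=O)cc1{a}",
    "O=C(NC1CCCCC1{a})c1cc2ccccc2o1",
    "CN1CCC(Oc2ccc(C#N)cc2{a})CC1",
    "OCC1OC(n2ccc(=O)[nH]c2=O)CC1{a}",
]
_CLUSTER_SUBSTITUENTS = ["", "C", "CC", "CCC", "OC", "F", "C(C)C", "CO", "CCO", "C(C)(C)C", "OCC", "CN"]

# (neutral base, salt SMILES) pairs: the salt strips back to the base's parent.
_SALT_PAIRS = [
    ("CCN(CC)CCc1ccccc1", "CCN(CC)CCc1ccccc1.Cl"),
    ("OC(=O)Cc1ccccc1", "[Na+].[O-]C(=O)Cc1ccccc1"),
    ("NCCc1ccc(OC)cc1", "NCCc1ccc(OC)cc1.OC(=O)C(=O)O"),
    ("OC(=O)c1ccc(C)cc1", "[K+].[O-]C(=O)c1ccc(C)cc1"),
]


def clean_pool(n: int, seed: int = 0) -> list[str]:
    """Deterministically enumerate up to ``n`` distinct drug-like SMILES."""
    out: list[str] = []
    seen: set[str] = set()
    combos = []
    for sc in _SCAFFOLDS:
        for a in _SUBSTITUENTS:
            for b in _SUBSTITUENTS:
                combos.append((sc, a, b))
    rng = random.Random(seed)
    rng.shuffle(combos)
    for sc, a, b in combos:
        smi = sc.replace("{a}", a).replace("{b}", b) if "{b}" in sc else sc.replace("{a}", a)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        out.append(can)
        if len(out) >= n:
            return out
    if len(out) < n:
        raise LibrankError(f"clean pool exhausted at {len(out)} < {n} molecules")
    return out


def generate_fixture_library(
    spec: Mapping[str, int], seed: int, name: str = "fixture"
) -> tuple[Library, dict[str, str]]:
    """Build a synthetic library with planted curation/alert categories.

    ``spec`` maps category names in {clean, salt-form, inorganic, mixture,
    duplicate-pair, alert-matching} to counts; a duplicate-pair plants two
    records sharing one parent structure.  Returns the library and a manifest
    mapping record_id -> category.  Pure function of (spec, seed).
    """
    allowed = {"clean", "salt-form", "inorganic", "mixture", "duplicate-pair", "alert-matching"}
    unknown = set(spec) - allowed
    if unknown:
        raise LibrankError(f"unknown fixture categories: {sorted(unknown)}")
    counts = {k: int(spec.get(k, 0)) for k in allowed}
    if any(v < 0 for v in counts.values()):
        raise LibrankError("fixture counts must be >= 0")
    if sum(counts.values()) == 0:
        raise LibrankError("fixture spec is empty: all counts are zero")

    rng = random.Random(seed)
    entries: list[tuple[str, str]] = []  # (smiles, category)

    pool = clean_pool(max(counts["clean"], 1) + 8, seed=rng.randrange(2**31))
    pool_iter = iter(pool)
    for _ in range(counts["clean"]):
        entries.append((next(pool_iter), "clean"))
    for i in range(counts["salt-form"]):
        _, salt = _SALT_PAIRS[i % len(_SALT_PAIRS)]
        entries.append((salt, "salt-form"))
    for i in range(counts["inorganic"]):
        entries.append((_INORGANICS[i % len(_INORGANICS)], "inorganic"))
    for i in range(counts["mixture"]):
        entries.append((_MIXTURES[i % len(_MIXTURES)], "mixture"))
    # offset so salt-form and duplicate-pair plants never share a parent
    dup_offset = counts["salt-form"]
    for i in range(counts["duplicate-pair"]):
        base, salt = _SALT_PAIRS[(i + dup_offset) % len(_SALT_PAIRS)]
        entries.append((base, "duplicate-pair"))
        entries.append((salt, "duplicate-pair"))
    for i in range(counts["alert-matching"]):
        entries.append((_ALERT_HITS[i % len(_ALERT_HITS)], "alert-matching"))

    rng.shuffle(entries)
    records, manifest = [], {}
    for i, (smi, cat) in enumerate(entries):
        rid = f"{name}-{i:04d}"
        mol, valence_ok = mol_from_smiles(smi)
        rec = _record_from_mol(mol, valence_ok, rid, name)
        records.append(rec)
        manifest[rid] = cat
    return Library(name=name, records=records, provenance=f"fixture(seed={seed})"), manifest


def generate_labeled_records(
    n_clusters: int, per_cluster: int, seed: int, name: str = "labeled"
) -> tuple[list[MoleculeRecord], list[str]]:
    """Synthetic analogue clusters with one label per cluster.

    Each cluster decorates one scaffold with different substituents, emulating
    a target-annotated reference database: within-cluster similarity is high,
    between-cluster similarity low.
    """
    if n_clusters > len(_CLUSTER_SCAFFOLDS):
        raise LibrankError(f"at most {len(_CLUSTER_SCAFFOLDS)} clusters supported")
    if per_cluster > len(_CLUSTER_SUBSTITUENTS):
        raise LibrankError(f"at most {len(_CLUSTER_SUBSTITUENTS)} members per cluster")
    rng = random.Random(seed)
    entries: list[tuple[str, str]] = []
    for c in range(n_clusters):
        sc = _CLUSTER_SCAFFOLDS[c]
        # small decorations on one large scaffold: tight cluster, one label
        for j in range(per_cluster):
            smi = sc.replace("{a}", _CLUSTER_SUBSTITUENTS[j])
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise LibrankError(f"cluster {c} member {j} failed to parse: {smi!r}")
            entries.append((Chem.MolToSmiles(mol), f"target-{c}"))
    rng.shuffle(entries)
    records, labels = [], []
    for i, (smi, lab) in enumerate(entries):
        records.append(
            MoleculeRecord(record_id=f"{name}-{i:04d}", source=name, mol=Chem.MolFromSmiles(smi))
        )
        labels.append(lab)
    return records, labels


#: Template for the planted-analogue similarity fixture: the reference and
#: its analogues differ only in the length of the O-alkyl chain, keeping
#: circular-fingerprint similarity to the reference high (> 0.7 with ECFP_4
#: for the first ~6 homologs) while typical decoys stay far below.
ANALOGUE_TEMPLATE = "O=C(Nc1ccccc1)c1ccc(OC{chain})cc1"
ANALOGUE_REFERENCE_CHAIN = 5


def analogue_series(n: int, template: str = ANALOGUE_TEMPLATE, base_chain: int = ANALOGUE_REFERENCE_CHAIN) -> tuple[str, list[str]]:
    """(reference SMILES, n chain-homolog analogues) from a template.

    The template must contain ``{chain}``; the reference uses ``base_chain``
    carbons and analogue i uses ``base_chain + i``.
    """
    def build(k: int) -> str:
        smi = template.replace("{chain}", "C" * k)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise LibrankError(f"analogue construction failed for {smi!r}")
        return Chem.MolToSmiles(mol)

    return build(base_chain), [build(base_chain + i) for i in range(1, n + 1)]


def records_from_smiles(smiles_list: Iterable[str], source: str = "adhoc") -> list[MoleculeRecord]:
    """Convenience: build records from an iterable of SMILES strings."""
    records = []
    for i, smi in enumerate(smiles_list):
        mol, valence_ok = mol_from_smiles(smi)
        if mol is None:
            raise LibrankError(f"bad SMILES at position {i}: {smi!r}")
        records.append(_record_from_mol(mol, valence_ok, f"{source}-{i:04d}", source))
    return records
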