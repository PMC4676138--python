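"""ADME/T profiling: Lipinski and Veber rule filters and a blood-brain
barrier permeation (logBB) model.

logBB is the log ratio of brain to blood concentration; compounds with
predicted logBB >= 0 are treated as BBB permeable, < 0 as impermeable.  The
shipped model is a linear-plus-spline regression over five 2D/3D
descriptors:

    logBB = 1.2827 + 0.17977*AlogP98 - 0.0033777*DPSA1
            - 0.18676*Num_H_Acceptors + 0.1557*S_sssN
            - 0.022135*<4.6743 - S_ssCH2>

where <x> = max(0, x) is the truncated-power spline basis used by genetic
function approximation, AlogP98 is an atom-contribution log partition
coefficient, DPSA1 the difference between partial-positive and
partial-negative solvent-accessible surface areas on one embedded conformer,
and S_sssN / S_ssCH2 are Kier-Hall electrotopological state sums over >N-
and -CH2- atoms.

Descriptor implementations here are open-source reconstructions (Crippen
logP for AlogP98; Gasteiger charges + FreeSASA on an ETKDG conformer for
DPSA1), so absolute logBB values for a given molecule can deviate from
implementations built on proprietary descriptor engines; the workflow
consumes only the permeable/impermeable fraction of a library.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdFreeSASA, rdMolDescriptors
from rdkit.Chem.EState import EStateIndices
from rdkit.Chem.EState.AtomTypes import TypeAtoms

from .chemio import DATA_DIR, Library, LibrankError, MoleculeRecord

logger = logging.getLogger("librank")

#: Fixed conformer-embedding seed: DPSA1 must be deterministic.
EMBED_SEED = 1987


class DescriptorError(LibrankError):
    pass


# ---------------------------------------------------------------------------
# rule-based filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyVector:
    mw: float
    clogp: float
    hbd: int
    hba: int
    rotb: int
    psa: float

    @property
    def hbond_count(self) -> int:
        return self.hbd + self.hba


def compute_properties(record: MoleculeRecord) -> PropertyVector:
    mol = record.mol
    return PropertyVector(
        mw=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        hbd=rdMolDescriptors.CalcNumLipinskiHBD(mol),
        hba=rdMolDescriptors.CalcNumLipinskiHBA(mol),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(mol),
        psa=rdMolDescriptors.CalcTPSA(mol),
    )


def lipinski_violations(props: PropertyVector) -> int:
    """Count of rule-of-five violations (strict inequalities).

    A compound fails the filter iff it violates more than one criterion.
    """
    return sum(
        [props.hbd > 5, props.mw > 500, props.clogp > 5, props.hba > 10]
    )


def lipinski_pass(props: PropertyVector) -> bool:
    return lipinski_violations(props) <= 1


def veber_pass(props: PropertyVector) -> bool:
    """Rotatable bonds <= 10 AND (PSA <= 140 A^2 OR H-bond count <= 12)."""
    return props.rotb <= 10 and (props.psa <= 140 or props.hbond_count <= 12)


# ---------------------------------------------------------------------------
# logBB model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogBBDescriptors:
    alogp98: float
    dpsa1: float
    num_h_acceptors: int
    s_sssN: float
    s_ssCH2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "AlogP98": self.alogp98,
            "DPSA1": self.dpsa1,
            "Num_H_Acceptors": self.num_h_acceptors,
            "S_sssN": self.s_sssN,
            "S_ssCH2": self.s_ssCH2,
        }


@dataclass
class LogBBModel:
    """Linear-plus-spline regression model, auditable as plain text.

    ``spline_terms`` entries are (descriptor, knot, coefficient, orientation)
    with orientation "below" meaning coefficient * max(0, knot - x) and
    "above" meaning coefficient * max(0, x - knot).
    """

    intercept: float
    linear_terms: list[tuple[str, float]] = field(default_factory=list)
    spline_terms: list[tuple[str, float, float, str]] = field(default_factory=list)

    def predict(self, descriptors: dict[str, float]) -> float:
        for name, value in descriptors.items():
            if not math.isfinite(value):
                raise DescriptorError(f"non-finite descriptor: {name}={value}")
        y = self.intercept
        for name, coef in self.linear_terms:
            y += coef * descriptors[name]
        for name, knot, coef, orientation in self.spline_terms:
            x = descriptors[name]
            arg = (knot - x) if orientation == "below" else (x - knot)
            y += coef * max(0.0, arg)
        return y

    def save(self, path: str | Path) -> None:
        lines = [f"intercept {self.intercept!r}"]
        for name, coef in self.linear_terms:
            lines.append(f"linear {name} {coef!r}")
        for name, knot, coef, orientation in self.spline_terms:
            lines.append(f"spline_{orientation} {name} {knot!r} {coef!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LogBBModel":
        intercept = 0.0
        linear: list[tuple[str, float]] = []
        splines: list[tuple[str, float, float, str]] = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            kind = parts[0]
            try:
                if kind == "intercept":
                    intercept = float(parts[1])
                elif kind == "linear":
                    linear.append((parts[1], float(parts[2])))
                elif kind in {"spline_below", "spline_above"}:
                    splines.append((parts[1], float(parts[2]), float(parts[3]), kind.split("_")[1]))
                else:
                    raise ValueError(kind)
            except (IndexError, ValueError) as exc:
                raise LibrankError(f"{path}:{lineno}: bad model line {line!r}") from exc
        return cls(intercept=intercept, linear_terms=linear, spline_terms=splines)


def default_logbb_model() -> LogBBModel:
    """The shipped logBB equation (see module docstring)."""
    return LogBBModel.load(DATA_DIR / "logbb_model.txt")


def predict_logbb(descriptors: LogBBDescriptors | dict, model: LogBBModel | None = None) -> float:
    model = model or default_logbb_model()
    d = descriptors.as_dict() if isinstance(descriptors, LogBBDescriptors) else dict(descriptors)
    return model.predict(d)


def classify_bbb(logbb: float) -> str:
    """'permeable' iff logBB >= 0 (boundary inclusive), else 'impermeable'."""
    if not math.isfinite(logbb):
        raise DescriptorError(f"non-finite logBB: {logbb}")
    return "permeable" if logbb >= 0 else "impermeable"


# ---------------------------------------------------------------------------
# descriptor computation
# ---------------------------------------------------------------------------

def _estate_sum(mol: Chem.Mol, atom_type: str) -> float:
    """Sum of E-state indices over atoms of the given Kier-Hall type."""
    types = TypeAtoms(mol)
    if not any(atom_type in t for t in types):
        return 0.0
    indices = EStateIndices(mol)
    return float(sum(v for v, t in zip(indices, types) if atom_type in t))


def _dpsa1(mol: Chem.Mol, seed: int = EMBED_SEED) -> float:
    """Partial-positive minus partial-negative solvent-accessible area.

    One ETKDG conformer (fixed seed), Gasteiger partial charges, FreeSASA
    per-atom areas summed by charge sign (hydrogens included).
    """
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise DescriptorError("conformer embedding failed")
    AllChem.ComputeGasteigerCharges(molh)
    radii = rdFreeSASA.classifyAtoms(molh)
    rdFreeSASA.CalcSASA(molh, radii)
    pos = neg = 0.0
    for atom in molh.GetAtoms():
        q = atom.GetDoubleProp("_GasteigerCharge")
        sasa = float(atom.GetProp("SASA"))
        if q > 0:
            pos += sasa
        elif q < 0:
            neg += sasa
    return pos - neg


def compute_logbb_descriptors(record: MoleculeRecord, seed: int = EMBED_SEED) -> LogBBDescriptors:
    mol = record.mol
    return LogBBDescriptors(
        alogp98=Crippen.MolLogP(mol),
        dpsa1=_dpsa1(mol, seed=seed),
        num_h_acceptors=rdMolDescriptors.CalcNumHBA(mol),
        s_sssN=_estate_sum(mol, "sssN"),
        s_ssCH2=_estate_sum(mol, "ssCH2"),
    )


# ---------------------------------------------------------------------------
# per-library report
# ---------------------------------------------------------------------------

def admet_report(library: Library, model: LogBBModel | None = None) -> pd.DataFrame:
    """Percent failing Lipinski, failing Veber and predicted logBB < 0.

    Records whose logBB descriptors cannot be computed (conformer embedding
    failure) are excluded from the BBB statistic only, with a logged count.
    """
    model = model or default_logbb_model()
    n = len(library.records)
    if n == 0:
        raise LibrankError(f"library {library.name} is empty")
    n_fail_lip = n_fail_veb = 0
    n_imperm = n_bbb = 0
    for rec in library.records:
        props = compute_properties(rec)
        if not lipinski_pass(props):
            n_fail_lip += 1
        if not veber_pass(props):
            n_fail_veb += 1
        try:
            d = compute_logbb_descriptors(rec)
        except DescriptorError:
            rec.flags["logbb_failed"] = True
            continue
        n_bbb += 1
        if classify_bbb(predict_logbb(d, model)) == "impermeable":
            n_imperm += 1
    n_failed = n - n_bbb
    if n_failed:
        logger.warning("library %s: %d records excluded from BBB statistics", library.name, n_failed)
    return pd.DataFrame(
        [
            {
                "library": library.name,
                "fail_lipinski_pct": 100.0 * n_fail_lip / n,
                "fail_veber_pct": 100.0 * n_fail_veb / n,
                "logbb_below_zero_pct": (100.0 * n_imperm / n_bbb) if n_bbb else float("nan"),
                "logbb_excluded_count": n_failed,
            }
        ]
    )
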