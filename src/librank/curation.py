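"""Library curation: salt stripping, removal of inorganics, mixtures,
bad-valence structures and duplicates, and structure standardization.

The stage mirrors common screening-library practice: every record is reduced
to its largest organic fragment when the discarded fragments are recognised
counter-ions, classified (inorganic -> mixture -> bad valence, first match
wins), standardized to one protonation state at physiological pH 7.4 and one
canonical tautomer, and de-duplicated on the canonical key of the parent
structure.  The per-category report gives counts and percentages relative to
the input size.

Protonation uses a small shipped pKa rule table (auditable SMARTS rules with
literature pKa values) rather than a full pKa predictor: deterministic,
idempotent and editable.  Tautomer choice uses a deterministic canonicalizer
with a fixed scoring of tautomers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chemio import DATA_DIR, Library, LibrankError, MoleculeRecord

logger = logging.getLogger("librank")

#: Elements allowed in an organic parent structure.
ORGANIC_ELEMENTS = frozenset(
    ["C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Se"]
)

#: A non-largest fragment with at most this many heavy atoms and zero or
#: opposite net charge is treated as a salt partner even when it is not in
#: the shipped counter-ion list.
SMALL_FRAGMENT_HEAVY_ATOMS = 6

_REMOVAL_CATEGORIES = ("inorganic", "duplicate", "mixture", "bad_valence")


def _load_counterions(path: Path | None = None) -> frozenset[str]:
    path = path or DATA_DIR / "counterions.smi"
    keys = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        mol = Chem.MolFromSmiles(line)
        if mol is None:
            raise LibrankError(f"bad counter-ion SMILES in {path.name}: {line!r}")
        keys.add(Chem.MolToSmiles(mol))
    return frozenset(keys)


_COUNTERIONS = _load_counterions()


@dataclass
class PkaRule:
    name: str
    kind: str  # acid | base
    pka: float
    pattern: Chem.Mol


def load_pka_rules(path: Path | None = None) -> list[PkaRule]:
    path = path or DATA_DIR / "pka_rules.tsv"
    rules = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise LibrankError(f"{path.name}:{lineno}: expected 4 tab-separated fields")
        name, kind, pka, smarts = parts
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise LibrankError(f"{path.name}:{lineno}: bad SMARTS {smarts!r}")
        if kind not in {"acid", "base"}:
            raise LibrankError(f"{path.name}:{lineno}: kind must be acid or base")
        rules.append(PkaRule(name, kind, float(pka), patt))
    return rules


_PKA_RULES = load_pka_rules()
_TAUTOMER_CANON = rdMolStandardize.TautomerEnumerator()
_NORMALIZER = rdMolStandardize.Normalizer()


# ---------------------------------------------------------------------------
# per-record operations
# ---------------------------------------------------------------------------

def _fragments(mol: Chem.Mol) -> list[Chem.Mol]:
    return list(Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False))


def _is_salt_partner(frag: Chem.Mol, parent_charge: int) -> bool:
    key = Chem.MolToSmiles(frag)
    if key in _COUNTERIONS:
        return True
    if frag.GetNumHeavyAtoms() <= SMALL_FRAGMENT_HEAVY_ATOMS:
        fc = Chem.GetFormalCharge(frag)
        if fc == 0 or fc * parent_charge <= 0:
            return True
    return False


def largest_fragment(record: MoleculeRecord) -> MoleculeRecord:
    """Strip recognised counter-ions, keeping the largest fragment.

    A multi-fragment record is reduced to its largest fragment only when all
    non-largest fragments look like salt partners (shipped counter-ion list,
    or small with zero/opposite charge).  Equal-size organic fragments are a
    tie and are left for mixture classification.
    """
    frags = _fragments(record.mol)
    if len(frags) <= 1:
        return record
    sizes = [f.GetNumHeavyAtoms() for f in frags]
    order = sorted(range(len(frags)), key=lambda i: sizes[i], reverse=True)
    if sizes[order[0]] == sizes[order[1]]:
        return record  # tie: not a salt
    parent = frags[order[0]]
    parent_charge = Chem.GetFormalCharge(parent)
    if all(_is_salt_partner(frags[i], parent_charge) for i in order[1:]):
        try:
            Chem.SanitizeMol(parent)
        except Exception:
            return record.with_mol(parent, bad_valence=True)
        return record.with_mol(parent, salt_stripped=True)
    return record


def _valence_ok(mol: Chem.Mol) -> bool:
    test = Chem.Mol(mol)
    try:
        Chem.SanitizeMol(test)
    except Exception:
        return False
    return True


def classify_record(record: MoleculeRecord) -> str:
    """Classify a (salt-stripped) record: inorganic, mixture, bad_valence, ok.

    Categories are checked in that order and the first match wins; inorganic
    is judged on the largest fragment so that e.g. simple inorganic salts are
    inorganic, not mixtures.
    """
    frags = _fragments(record.mol)
    parent = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    symbols = {a.GetSymbol() for a in parent.GetAtoms()}
    if "C" not in symbols or not symbols <= ORGANIC_ELEMENTS:
        return "inorganic"
    if len(frags) > 1:
        return "mixture"
    if record.flags.get("bad_valence") or not _valence_ok(record.mol):
        return "bad_valence"
    return "ok"


def _apply_pka_rules(mol: Chem.Mol, ph: float = 7.4) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    changed = False
    for rule in _PKA_RULES:
        fire = (rule.kind == "acid" and rule.pka < ph) or (rule.kind == "base" and rule.pka > ph)
        if not fire:
            continue
        # re-match after each rule so edits are visible to later rules
        matches = rw.GetMol().GetSubstructMatches(rule.pattern)
        for match in matches:
            atom = rw.GetAtomWithIdx(match[0])
            if rule.kind == "acid":
                if atom.GetTotalNumHs() < 1:
                    continue
                atom.SetFormalCharge(atom.GetFormalCharge() - 1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
                atom.SetNoImplicit(True)
            else:
                atom.SetFormalCharge(atom.GetFormalCharge() + 1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
            changed = True
    out = rw.GetMol()
    if changed:
        Chem.SanitizeMol(out)
    return out


def standardize(record: MoleculeRecord, ph: float = 7.4) -> MoleculeRecord:
    """Normalize, set protonation at the given pH, pick one canonical tautomer.

    Idempotent: standardize(standardize(r)) == standardize(r); the pKa rules
    are written so transformed groups no longer match their own pattern.
    """
    mol = _NORMALIZER.normalize(record.mol)
    Chem.SanitizeMol(mol)
    mol = _TAUTOMER_CANON.Canonicalize(mol)
    mol = _apply_pka_rules(mol, ph=ph)
    return record.with_mol(mol, standardized=True)


def deduplicate(records: list[MoleculeRecord]) -> tuple[list[MoleculeRecord], int]:
    """Keep the first occurrence of each canonical key, in input order."""
    seen: set[str] = set()
    kept = []
    removed = 0
    for rec in records:
        if rec.canonical_key in seen:
            removed += 1
        else:
            seen.add(rec.canonical_key)
            kept.append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# whole-library curation
# ---------------------------------------------------------------------------

@dataclass
class CurationReport:
    """Per-category removal counts and percentages for one library."""

    library: str
    total_in: int
    counts: dict = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return sum(self.counts.get(c, 0) for c in _REMOVAL_CATEGORIES)

    @property
    def total_out(self) -> int:
        return self.total_in - self.total_removed

    def pct(self, category: str) -> float:
        if self.total_in == 0:
            return 0.0
        return 100.0 * self.counts.get(category, 0) / self.total_in

    @property
    def total_removed_pct(self) -> float:
        return 0.0 if self.total_in == 0 else 100.0 * self.total_removed / self.total_in

    def to_frame(self) -> pd.DataFrame:
        row = {"library": self.library, "total_in": self.total_in}
        for c in _REMOVAL_CATEGORIES + ("parse_failure",):
            row[f"{c}_count"] = self.counts.get(c, 0)
            row[f"{c}_pct"] = round(self.pct(c), 4)
        row["total_out"] = self.total_out
        row["total_removed_pct"] = round(self.total_removed_pct, 4)
        return pd.DataFrame([row])


def curate(library: Library, ph: float = 7.4) -> tuple[Library, CurationReport]:
    """Run the full curation pipeline on a library.

    Order: salt stripping -> classification (non-ok removed) -> protonation/
    tautomer standardization -> de-duplication.  Percentages are relative to
    the library's input size; parse failures recorded at read time are
    carried into the report but (being absent from the parsed records) do not
    enter the removal arithmetic.
    """
    report = CurationReport(library=library.name, total_in=len(library.records))
    report.counts["parse_failure"] = library.parse_failures

    survivors: list[MoleculeRecord] = []
    for rec in library.records:
        rec = largest_fragment(rec)
        category = classify_record(rec)
        if category != "ok":
            report.counts[category] = report.counts.get(category, 0) + 1
            continue
        survivors.append(standardize(rec, ph=ph))

    kept, n_dup = deduplicate(survivors)
    report.counts["duplicate"] = n_dup
    if not kept:
        logger.warning("library %s: curation removed every record", library.name)
    curated = Library(
        name=library.name,
        records=kept,
        provenance=library.provenance,
        parse_failures=0,
    )
    return curated, report
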