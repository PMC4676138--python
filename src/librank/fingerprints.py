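"""2D fingerprint dialects and Tanimoto similarity.

Three families are supported, in binary and count forms:

* circular extended-connectivity fingerprints, ECFP_n (element/connectivity
  atom invariants) and FCFP_n (functional-class invariants), with diameter
  n in {2, 4, 6} — sparse feature-id sets, no bit folding, stable hashing;
* MDL public structural keys (the standard 166-key dictionary);
* topological n-point pharmacophore fingerprints (n in {2, 3, 4}): features
  are sorted tuples of pharmacophoric feature types together with binned
  shortest-path distances between the feature atoms.

The pharmacophore dialect grid follows the PH{F,PF,RF}{P,C}_n naming: the
middle letters select the feature-type palette (F = the full six-type
palette; PF = a coarse three-type palette merging ionizable into donor/
acceptor and aromatic into hydrophobe; RF = a fine palette splitting
hydrophobes and adding halogens) and the final letter selects binary (P)
versus count (C) form.  Feature definitions are shipped as an editable
SMARTS file.

Tanimoto over binary fingerprints is |A∩B|/|A∪B|; over count fingerprints
it is sum(min)/sum(max) across the feature union.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chemio import DATA_DIR, LibrankError, MoleculeRecord

#: Every dialect tag the diversity/similarity protocols may iterate over.
ALL_DIALECTS = (
    ["ECFP_2", "ECFP_4", "ECFP_6", "FCFP_2", "FCFP_4", "FCFP_6", "MDL_keys"]
    + [f"PH{fam}{form}_{n}" for fam in ("F", "PF", "RF") for form in ("P", "C") for n in (2, 3, 4)]
)

#: Topological distance bins: 1 | 2 | 3 | 4 | 5 | 6-7 | 8-10 | >10.
#: Fully distance-resolved at short range so that e.g. para- and meta-
#: substitution patterns map to different features.
DISTANCE_BIN_EDGES = (1, 2, 3, 4, 5, 7, 10)


@dataclass(frozen=True)
class Fingerprint:
    """Sparse fingerprint: feature id -> count (1 for binary dialects)."""

    dialect: str
    form: str  # "binary" | "count"
    data: dict
    flagged: bool = False  # molecule lacked the features the dialect needs

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> frozenset:
        return frozenset(self.data)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    if a.dialect != b.dialect:
        raise LibrankError(f"dialect mismatch: {a.dialect} vs {b.dialect}")
    if not a.data and not b.data:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0", stacklevel=2)
        return 0.0
    if a.form == "binary":
        fa, fb = a.features, b.features
        return len(fa & fb) / len(fa | fb)
    num = den = 0
    for key in a.features | b.features:
        ca, cb = a.data.get(key, 0), b.data.get(key, 0)
        num += min(ca, cb)
        den += max(ca, cb)
    return num / den


# ---------------------------------------------------------------------------
# circular and structural-key fingerprints
# ---------------------------------------------------------------------------

def circular_fp(record: MoleculeRecord, diameter: int, functional_class: bool = False) -> Fingerprint:
    """ECFP/FCFP sparse count fingerprint of the given diameter.

    Feature ids are canonical environment hashes: identical environments get
    identical ids regardless of diameter, so the feature set at diameter 2
    is nested inside those at diameters 4 and 6.
    """
    if diameter not in (2, 4, 6):
        raise LibrankError(f"diameter must be 2, 4 or 6, got {diameter}")
    kwargs = {"radius": diameter // 2, "includeChirality": False}
    if functional_class:
        kwargs["atomInvariantsGenerator"] = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
    gen = rdFingerprintGenerator.GetMorganGenerator(**kwargs)
    counts = gen.GetSparseCountFingerprint(record.mol).GetNonzeroElements()
    tag = ("FCFP_" if functional_class else "ECFP_") + str(diameter)
    return Fingerprint(dialect=tag, form="count", data=dict(counts))


def structural_keys(record: MoleculeRecord) -> Fingerprint:
    """166-key MDL public structural keys (binary)."""
    bv = MACCSkeys.GenMACCSKeys(record.mol)
    return Fingerprint(dialect="MDL_keys", form="binary", data={b: 1 for b in bv.GetOnBits()})


# ---------------------------------------------------------------------------
# pharmacophore fingerprints
# ---------------------------------------------------------------------------

_BASE_TYPES = ("donor", "acceptor", "pos_ionizable", "neg_ionizable", "aromatic", "hydrophobe")

# palette -> mapping of base feature type to palette type (None drops it)
_PALETTES: dict[str, dict[str, str | None]] = {
    # full six-type palette
    "F": {t: t for t in _BASE_TYPES} | {"halogen": None},
    # coarse: ionizables merged into donor/acceptor, aromatic into hydrophobe
    "PF": {
        "donor": "donor",
        "pos_ionizable": "donor",
        "acceptor": "acceptor",
        "neg_ionizable": "acceptor",
        "aromatic": "hydrophobe",
        "hydrophobe": "hydrophobe",
        "halogen": None,
    },
    # fine: aromatic rings distinct from aliphatic hydrophobes, plus halogens
    "RF": {t: t for t in _BASE_TYPES} | {"halogen": "halogen"},
}


def _load_feature_defs(path: Path | None = None) -> list[tuple[str, Chem.Mol]]:
    path = path or DATA_DIR / "pharmacophore_features.smarts"
    defs = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LibrankError(f"{path.name}:{lineno}: expected type<TAB>SMARTS")
        patt = Chem.MolFromSmarts(parts[1])
        if patt is None:
            raise LibrankError(f"{path.name}:{lineno}: bad SMARTS {parts[1]!r}")
        defs.append((parts[0], patt))
    return defs


_FEATURE_DEFS = _load_feature_defs()


def _feature_points(mol: Chem.Mol, palette: str) -> list[tuple[str, frozenset[int]]]:
    """(palette type, atom-index set) pairs.

    Single-atom features carry one index; aromatic features are per-ring and
    carry the whole ring.  Distances between features are minima over their
    atom sets, which keeps fingerprints invariant to atom numbering.
    """
    mapping = _PALETTES[palette]
    points: set[tuple[str, frozenset[int]]] = set()
    for base_type, patt in _FEATURE_DEFS:
        ptype = mapping.get(base_type)
        if ptype is None:
            continue
        if base_type == "aromatic":
            continue  # handled ring-wise below
        for match in mol.GetSubstructMatches(patt):
            points.add((ptype, frozenset([match[0]])))
    aromatic_target = mapping.get("aromatic")
    if aromatic_target is not None:
        for ring in mol.GetRingInfo().AtomRings():
            if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                points.add((aromatic_target, frozenset(ring)))
    return sorted(points, key=lambda p: (p[0], sorted(p[1])))


def _bin_distance(d: int) -> int:
    for b, edge in enumerate(DISTANCE_BIN_EDGES):
        if d <= edge:
            return b
    return len(DISTANCE_BIN_EDGES)


def _canonical_feature(types: tuple[str, ...], bins: list[list[int]]):
    """Lexicographically minimal (types, binned-distance-vector) over all
    orderings of the points — invariant to atom numbering."""
    best = None
    k = len(types)
    for perm in itertools.permutations(range(k)):
        t = tuple(types[p] for p in perm)
        d = tuple(bins[perm[i]][perm[j]] for i in range(k) for j in range(i + 1, k))
        cand = (t, d)
        if best is None or cand < best:
            best = cand
    return best


def pharmacophore_fp(
    record: MoleculeRecord, points: int, form: str = "binary", palette: str = "F"
) -> Fingerprint:
    """Topological n-point pharmacophore fingerprint.

    Molecules with fewer than ``points`` pharmacophoric features yield an
    empty, flagged fingerprint (such compounds are excluded from statistics
    by the callers, mirroring how reference databases drop compounds whose
    descriptors cannot be calculated).
    """
    if points not in (2, 3, 4):
        raise LibrankError("points must be 2, 3 or 4")
    if form not in ("binary", "count"):
        raise LibrankError("form must be 'binary' or 'count'")
    tag = f"PH{palette}{'P' if form == 'binary' else 'C'}_{points}"
    feats = _feature_points(record.mol, palette)
    if len(feats) < points:
        return Fingerprint(dialect=tag, form=form, data={}, flagged=True)
    dmat = Chem.GetDistanceMatrix(record.mol)
    # min-over-atom-sets distance between every feature pair, binned
    nfeat = len(feats)
    bins = [[0] * nfeat for _ in range(nfeat)]
    for i in range(nfeat):
        for j in range(i + 1, nfeat):
            d = min(int(dmat[a][b]) for a in feats[i][1] for b in feats[j][1])
            bins[i][j] = bins[j][i] = _bin_distance(d)
    data: dict = {}
    for combo in itertools.combinations(range(nfeat), points):
        sets = [feats[c][1] for c in combo]
        if any(sets[i] & sets[j] for i in range(points) for j in range(i + 1, points)):
            continue  # features must occupy disjoint atom sets
        types = tuple(feats[c][0] for c in combo)
        sub = [[bins[a][b] for b in combo] for a in combo]
        key = _canonical_feature(types, sub)
        data[key] = data.get(key, 0) + 1
    if form == "binary":
        data = {k: 1 for k in data}
    return Fingerprint(dialect=tag, form=form, data=data, flagged=not data)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def fingerprint(record: MoleculeRecord, dialect: str) -> Fingerprint:
    """Compute the fingerprint named by any of the supported dialect tags."""
    if dialect.startswith(("ECFP_", "FCFP_")):
        return circular_fp(record, int(dialect[-1]), functional_class=dialect.startswith("FCFP"))
    if dialect in ("MDL_keys", "MDL"):
        return structural_keys(record)
    if dialect.startswith("PH"):
        stem, n = dialect.rsplit("_", 1)
        form = {"P": "binary", "C": "count"}.get(stem[-1])
        palette = stem[2:-1]
        if form is None or palette not in _PALETTES:
            raise LibrankError(f"unknown pharmacophore dialect: {dialect}")
        return pharmacophore_fp(record, int(n), form=form, palette=palette)
    raise LibrankError(f"unknown fingerprint dialect: {dialect}")
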