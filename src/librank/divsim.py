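"""Diversity and similarity analysis over fingerprint spaces.

Covers: mean pairwise Tanimoto similarity as an (inverse) internal-diversity
score, greedy MaxMin diverse-subset selection, target/indication coverage
curves for benchmarking diversity descriptors, similarity ranking with
enrichment curves for benchmarking similarity descriptors, threshold and
variable-atom substructure searches, and cross-library overlap at a Tanimoto
cutoff.

Records whose fingerprint is empty/flagged for a dialect (e.g. too few
pharmacophoric features for an n-point fingerprint) are excluded from that
metric only, with a logged count.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from rdkit import Chem

from .chemio import Library, LibrankError, MoleculeRecord
from .fingerprints import Fingerprint, fingerprint, tanimoto

logger = logging.getLogger("librank")


def _usable_fps(records: list[MoleculeRecord], dialect: str) -> tuple[list[int], list[Fingerprint]]:
    idx, fps = [], []
    skipped = 0
    for i, rec in enumerate(records):
        f = fingerprint(rec, dialect)
        if f.flagged or not f.data:
            skipped += 1
            continue
        idx.append(i)
        fps.append(f)
    if skipped:
        logger.info("%d records lack %s features and are excluded", skipped, dialect)
    return idx, fps


# ---------------------------------------------------------------------------
# internal diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanSimilarity:
    value: float
    n_pairs: int
    exhaustive: bool

    def __float__(self) -> float:
        return self.value


def mean_pairwise_similarity(
    records: list[MoleculeRecord] | Library,
    dialect: str,
    max_pairs: int | None = None,
    seed: int = 0,
) -> MeanSimilarity:
    """Mean Tanimoto over all unordered pairs (lower = more diverse).

    When the pair count exceeds ``max_pairs``, an unbiased uniform sample of
    pairs (with replacement, seeded) estimates the mean; the result reports
    the number of pairs actually evaluated.
    """
    records = list(records)
    _, fps = _usable_fps(records, dialect)
    n = len(fps)
    if n < 2:
        raise LibrankError("mean pairwise similarity needs >= 2 usable records")
    n_pairs = n * (n - 1) // 2
    if max_pairs is None or n_pairs <= max_pairs:
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                total += tanimoto(fps[i], fps[j])
        return MeanSimilarity(total / n_pairs, n_pairs, True)
    rng = random.Random(seed)
    total = 0.0
    for _ in range(max_pairs):
        i = rng.randrange(n)
        j = rng.randrange(n - 1)
        if j >= i:
            j += 1
        total += tanimoto(fps[i], fps[j])
    return MeanSimilarity(total / max_pairs, max_pairs, False)


def maxmin_select(
    records: list[MoleculeRecord] | Library,
    dialect: str,
    k: int,
    seed: int | None = None,
    first_index: int | None = None,
) -> list[int]:
    """Greedy MaxMin diverse-subset selection; returns indices into ``records``.

    Distance is 1 - Tanimoto.  The first pick is, by default, the record with
    the maximal mean distance to all others (deterministic); passing ``seed``
    instead picks a seeded random start, and ``first_index`` forces one.
    Each subsequent pick maximizes its minimum distance to the selected set;
    ties break by input order.  Records without usable fingerprints are never
    selected.
    """
    records = list(records)
    idx, fps = _usable_fps(records, dialect)
    n = len(fps)
    if not 1 <= k <= n:
        raise LibrankError(f"k must be in [1, {n}], got {k}")

    if first_index is not None:
        first = idx.index(first_index)
    elif seed is not None:
        first = random.Random(seed).randrange(n)
    else:
        best_mean, first = None, 0
        for i in range(n):
            m = sum(1.0 - tanimoto(fps[i], fps[j]) for j in range(n) if j != i)
            if best_mean is None or m > best_mean:
                best_mean, first = m, i

    selected = [first]
    min_dist = [1.0 - tanimoto(fps[first], fps[j]) for j in range(n)]
    min_dist[first] = -1.0
    while len(selected) < k:
        pick = max((i for i in range(n) if min_dist[i] >= 0), key=lambda i: min_dist[i])
        selected.append(pick)
        for j in range(n):
            if min_dist[j] >= 0:
                d = 1.0 - tanimoto(fps[pick], fps[j])
                if d < min_dist[j]:
                    min_dist[j] = d
        min_dist[pick] = -1.0
    return [idx[i] for i in selected]


# ---------------------------------------------------------------------------
# labeled sets and coverage curves
# ---------------------------------------------------------------------------

@dataclass
class LabeledSet:
    """Records with one target/indication label each.

    ``from_multilabel`` reproduces the usual reference-database preprocessing:
    drop records classified to more than a single label, then drop labels
    with fewer than ``min_label_members`` records.
    """

    records: list[MoleculeRecord]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise LibrankError("records and labels must align")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_labels(self) -> int:
        return len(set(self.labels))

    @classmethod
    def from_multilabel(
        cls,
        records: list[MoleculeRecord],
        label_lists: list[list[str]],
        min_label_members: int = 2,
    ) -> "LabeledSet":
        singles = [(r, ls[0]) for r, ls in zip(records, label_lists) if len(ls) == 1]
        counts: dict[str, int] = {}
        for _, lab in singles:
            counts[lab] = counts.get(lab, 0) + 1
        kept = [(r, lab) for r, lab in singles if counts[lab] >= min_label_members]
        return cls(records=[r for r, _ in kept], labels=[lab for _, lab in kept])


@dataclass
class CoverageCurve:
    """(subset size, % labels covered) points, sizes strictly increasing."""

    points: list[tuple[int, float]] = field(default_factory=list)

    @property
    def mean_coverage(self) -> float:
        return sum(p[1] for p in self.points) / len(self.points)


def coverage_curve(
    labeled: LabeledSet,
    dialect: str,
    sizes: list[int],
    seed: int | None = None,
    random_baseline: bool = False,
    n_replicates: int = 10,
) -> CoverageCurve:
    """Percent of distinct labels covered by subsets of the given sizes.

    Subsets come from one nested MaxMin run (greedy prefixes), so coverage is
    monotone in size; with ``random_baseline`` they are uniform random draws
    instead, averaged over ``n_replicates`` seeded replicates.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 1 or sizes[-1] > len(labeled):
        raise LibrankError(f"sizes must lie within [1, {len(labeled)}]")
    n_labels = labeled.n_labels
    points: list[tuple[int, float]] = []
    if random_baseline:
        rng = random.Random(seed if seed is not None else 0)
        for size in sizes:
            cov = 0.0
            for _ in range(n_replicates):
                chosen = rng.sample(range(len(labeled)), size)
                cov += 100.0 * len({labeled.labels[i] for i in chosen}) / n_labels
            points.append((size, cov / n_replicates))
        return CoverageCurve(points)
    order = maxmin_select(labeled.records, dialect, k=sizes[-1], seed=seed)
    for size in sizes:
        covered = {labeled.labels[i] for i in order[:size]}
        points.append((size, 100.0 * len(covered) / n_labels))
    return CoverageCurve(points)


# ---------------------------------------------------------------------------
# similarity ranking and enrichment
# ---------------------------------------------------------------------------

@dataclass
class RankedList:
    """Library indices in descending similarity order, with scores.

    ``tied[i]`` is True when entry i shares its score with a neighbour;
    within a tied block the input order is preserved (stable sort).
    """

    indices: list[int]
    scores: list[float]
    tied: list[bool]


def rank_by_similarity(
    records: list[MoleculeRecord] | Library, reference: MoleculeRecord, dialect: str
) -> RankedList:
    records = list(records)
    ref_fp = fingerprint(reference, dialect)
    if not ref_fp.data:
        raise LibrankError("reference fingerprint is empty for this dialect")
    idx, fps = _usable_fps(records, dialect)
    scores = [tanimoto(ref_fp, f) for f in fps]
    order = sorted(range(len(idx)), key=lambda i: -scores[i])  # stable
    sorted_scores = [scores[i] for i in order]
    tied = [
        (i > 0 and sorted_scores[i] == sorted_scores[i - 1])
        or (i + 1 < len(order) and sorted_scores[i] == sorted_scores[i + 1])
        for i in range(len(order))
    ]
    return RankedList(indices=[idx[i] for i in order], scores=sorted_scores, tied=tied)


@dataclass
class EnrichmentCurve:
    """(% library screened, % actives recovered) points, ending at (100, 100).

    Tied-score blocks contribute single endpoints, so the drawn curve is the
    straight line across each block.  ``auc`` is the trapezoid-rule area on
    the [0, 1] x [0, 1] scale; 0.5 is random, 1 is perfect early recovery.
    """

    points: list[tuple[float, float]]
    auc: float


def enrichment_curve(ranked: RankedList, active_flags: list[bool]) -> EnrichmentCurve:
    """Cumulative actives-recovered curve for a ranked library.

    ``active_flags`` aligns with the *original* record positions referenced
    by ``ranked.indices``.
    """
    n = len(ranked.indices)
    n_act = sum(bool(active_flags[i]) for i in ranked.indices)
    if n_act == 0:
        raise LibrankError("enrichment curve needs at least one active")
    points = [(0.0, 0.0)]
    screened = found = 0
    i = 0
    while i < n:
        j = i
        while j < n and ranked.scores[j] == ranked.scores[i]:
            j += 1
        found += sum(bool(active_flags[k]) for k in ranked.indices[i:j])
        screened += j - i
        points.append((100.0 * screened / n, 100.0 * found / n_act))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return EnrichmentCurve(points=points, auc=auc / 10000.0)


# ---------------------------------------------------------------------------
# searches and cross-library comparison
# ---------------------------------------------------------------------------

def threshold_search(
    records: list[MoleculeRecord] | Library,
    reference: MoleculeRecord,
    dialect: str,
    threshold: float,
) -> list[int]:
    """Indices of records with Tanimoto >= threshold to the reference."""
    if not 0.0 <= threshold <= 1.0:
        raise LibrankError("threshold must be in [0, 1]")
    records = list(records)
    ref_fp = fingerprint(reference, dialect)
    out = []
    for i, rec in enumerate(records):
        f = fingerprint(rec, dialect)
        if not f.data and not ref_fp.data:
            continue
        if not f.data:
            if threshold == 0.0:
                out.append(i)
            continue
        if tanimoto(ref_fp, f) >= threshold:
            out.append(i)
    return out


@dataclass
class SubstructureQuery:
    """A substructure query, optionally with one variable atom.

    A variable atom is a position allowed to be any element of a list; the
    query expands into one concrete SMARTS per allowed element (written from
    a template containing the placeholder ``{X}``) and a record matches if
    any expansion is a subgraph match.
    """

    patterns: list[Chem.Mol]
    smarts: list[str]

    @classmethod
    def from_smarts(cls, smarts: str) -> "SubstructureQuery":
        if "{X}" in smarts:
            raise LibrankError("template with variable atom needs from_template(elements=...)")
        return cls.from_template(smarts, [])

    @classmethod
    def from_template(cls, template: str, elements: list[str]) -> "SubstructureQuery":
        if "{X}" in template:
            if not elements:
                raise LibrankError("variable-atom template needs a non-empty element list")
            expanded = [template.replace("{X}", el) for el in elements]
        else:
            expanded = [template]
        patterns = []
        for sm in expanded:
            patt = Chem.MolFromSmarts(sm)
            if patt is None:
                raise LibrankError(f"invalid substructure query: {sm!r}")
            patterns.append(patt)
        return cls(patterns=patterns, smarts=expanded)


def substructure_search(
    records: list[MoleculeRecord] | Library, query: SubstructureQuery | str
) -> list[int]:
    """Indices of records matching the (possibly variable-atom) query."""
    if isinstance(query, str):
        query = SubstructureQuery.from_smarts(query)
    records = list(records)
    return [
        i
        for i, rec in enumerate(records)
        if any(rec.mol.HasSubstructMatch(p) for p in query.patterns)
    ]


def compare_libraries(
    candidate: Library,
    in_house: Library,
    dialect: str = "ECFP_4",
    threshold: float = 0.7,
) -> tuple[int, float]:
    """Candidate records whose best Tanimoto against the in-house library
    reaches the threshold: (count, percent of candidate size, 1 decimal).

    Exact all-pairs computation; deliberately not symmetric (overlap is
    measured relative to the candidate library).
    """
    if not candidate.records or not in_house.records:
        raise LibrankError("both libraries must be non-empty")
    _, house_fps = _usable_fps(in_house.records, dialect)
    count = 0
    for rec in candidate.records:
        f = fingerprint(rec, dialect)
        if not f.data:
            continue
        if any(tanimoto(f, hf) >= threshold for hf in house_fps):
            count += 1
    pct = round(100.0 * count / len(candidate.records), 1)
    return count, pct
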