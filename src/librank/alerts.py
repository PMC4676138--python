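"""Promiscuous-binder / frequent-HTS-hitter substructure alerts.

Compounds matching PAINS-style substructure classes tend to show up as
false positives across many assays.  The workflow flags them (it never
deletes compounds) and reports the flagged percentage per library as a
selection criterion.  The catalog is a plain text file of named SMARTS and
is fully replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chemio import DATA_DIR, Library, LibrankError, MoleculeRecord


@dataclass
class AlertCatalog:
    """Ordered list of (name, compiled SMARTS) alert entries."""

    entries: list[tuple[str, Chem.Mol]]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]


def load_catalog(path: str | Path) -> AlertCatalog:
    """Load a "name<TAB>SMARTS" catalog; '#' starts a comment.

    Invalid SMARTS or duplicate names are fatal (with line numbers); an
    empty catalog is fatal.
    """
    path = Path(path)
    entries: list[tuple[str, Chem.Mol]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LibrankError(f"{path}:{lineno}: expected name<TAB>SMARTS")
        name, smarts = parts[0].strip(), parts[1].strip()
        if name in seen:
            raise LibrankError(f"{path}:{lineno}: duplicate alert name {name!r}")
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise LibrankError(f"{path}:{lineno}: invalid SMARTS {smarts!r}")
        seen.add(name)
        entries.append((name, patt))
    if not entries:
        raise LibrankError(f"{path}: empty alert catalog")
    return AlertCatalog(entries=entries)


def default_catalog() -> AlertCatalog:
    return load_catalog(DATA_DIR / "alerts_default.smarts")


def flag_promiscuous(record: MoleculeRecord, catalog: AlertCatalog) -> list[str]:
    """All matching alert names, in catalog order."""
    return [name for name, patt in catalog.entries if record.mol.HasSubstructMatch(patt)]


def library_promiscuity_fraction(library: Library, catalog: AlertCatalog) -> float:
    """Percent of records with at least one alert (each record counted once)."""
    if len(library.records) == 0:
        raise LibrankError(f"library {library.name} is empty")
    n_flagged = sum(1 for rec in library.records if flag_promiscuous(rec, catalog))
    return 100.0 * n_flagged / len(library.records)


def alert_report(library: Library, catalog: AlertCatalog | None = None) -> pd.DataFrame:
    catalog = catalog or default_catalog()
    per_alert: dict[str, int] = {name: 0 for name in catalog.names}
    n_flagged = 0
    for rec in library.records:
        hits = flag_promiscuous(rec, catalog)
        if hits:
            n_flagged += 1
        for h in hits:
            per_alert[h] += 1
    row = {
        "library": library.name,
        "promiscuous_pct": 100.0 * n_flagged / len(library.records),
        "flagged_count": n_flagged,
    }
    return pd.DataFrame([row])
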