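"""Reading, validation and writing of Y-STR haplotype tables.

The data model is deliberately small: a :class:`LocusPanel` fixes the marker
set and per-locus mutation rates, a :class:`Haplotype` holds one sample's
integer repeat counts plus population metadata, and a :class:`HaplotypeSet`
bundles haplotypes sharing a panel.  Two-copy markers (DYS385-type) are stored
as unordered pairs and expanded into two sorted "columns" internally, so that
every downstream computation sees a flat vector of repeat values with NaN for
missing data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample_id", "population", "district", "ancient", "snp_branch")

#: number of repeat values carried by a multicopy marker
MULTICOPY_ARITY = 2


@dataclass(frozen=True)
class LocusPanel:
    """An ordered Y-STR marker panel with per-locus mutation rates.

    Parameters
    ----------
    loci:
        Ordered marker names, unique.
    mu:
        Mutation rate per locus per generation.  A scalar applies uniformly;
        a mapping gives per-locus rates.
    multicopy:
        Names of markers carrying :data:`MULTICOPY_ARITY` repeat values each
        (e.g. DYS385); each contributes that many columns to the expanded
        representation.
    """

    loci: tuple[str, ...]
    mu: Mapping[str, float] = 0.0039
    multicopy: frozenset[str] = frozenset()

    def __post_init__(self):
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")
        if isinstance(self.mu, (int, float)):
            object.__setattr__(self, "mu", {n: float(self.mu) for n in self.loci})
        else:
            object.__setattr__(self, "mu", dict(self.mu))
        missing = set(self.loci) - set(self.mu)
        if missing:
            raise ValueError(f"no mutation rate for loci: {sorted(missing)}")
        if any(self.mu[n] <= 0 for n in self.loci):
            raise ValueError("all mutation rates must be positive")
        object.__setattr__(self, "multicopy", frozenset(self.multicopy))
        unknown = self.multicopy - set(self.loci)
        if unknown:
            raise ValueError(f"multicopy flags for unknown loci: {sorted(unknown)}")

    # -- expanded column view -------------------------------------------------

    @property
    def columns(self) -> tuple[str, ...]:
        """Expanded column names; multicopy marker X appears as X:1, X:2."""
        cols: list[str] = []
        for name in self.loci:
            if name in self.multicopy:
                cols.extend(f"{name}:{i + 1}" for i in range(MULTICOPY_ARITY))
            else:
                cols.append(name)
        return tuple(cols)

    @property
    def column_locus(self) -> tuple[str, ...]:
        """Parent locus name of each expanded column."""
        out: list[str] = []
        for name in self.loci:
            arity = MULTICOPY_ARITY if name in self.multicopy else 1
            out.extend([name] * arity)
        return tuple(out)

    @property
    def L(self) -> int:
        """Total repeat-value count (multicopy copies counted separately)."""
        return len(self.columns)

    @property
    def column_mu(self) -> np.ndarray:
        return np.array([self.mu[loc] for loc in self.column_locus])

    @property
    def mean_mu(self) -> float:
        return float(self.column_mu.mean())

    # -- encoding -------------------------------------------------------------

    def encode(self, repeats: Mapping[str, object]) -> np.ndarray:
        """Encode a repeats mapping into a float vector with NaN for missing.

        Multicopy values are sorted so that comparison of two vectors column
        by column realizes the minimum-cost assignment between the multisets.
        """
        vec = np.full(self.L, np.nan)
        pos = 0
        for name in self.loci:
            arity = MULTICOPY_ARITY if name in self.multicopy else 1
            val = repeats.get(name)
            if val is not None:
                if arity == 1:
                    vec[pos] = float(val)
                else:
                    vals = sorted(val) if isinstance(val, (tuple, list)) else None
                    if vals is not None and len(vals) == arity:
                        vec[pos:pos + arity] = [float(v) for v in vals]
                    # wrong arity -> left missing
            pos += arity
        return vec

    def decode(self, vec: Sequence[float]) -> dict[str, object]:
        """Inverse of :meth:`encode` (NaN columns dropped)."""
        out: dict[str, object] = {}
        pos = 0
        for name in self.loci:
            arity = MULTICOPY_ARITY if name in self.multicopy else 1
            vals = vec[pos:pos + arity]
            if not any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
                out[name] = int(vals[0]) if arity == 1 else tuple(sorted(int(v) for v in vals))
            pos += arity
        return out

    # -- serialization --------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "LocusPanel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: Mapping) -> "LocusPanel":
        default_mu = float(doc.get("default_mu", 0.0039))
        loci, mu, multi = [], {}, set()
        for name, spec in doc["loci"].items():
            spec = spec or {}
            loci.append(str(name))
            mu[str(name)] = float(spec.get("mu", default_mu))
            if spec.get("multicopy"):
                multi.add(str(name))
        return cls(tuple(loci), mu, frozenset(multi))

    def to_yaml(self, path) -> None:
        doc = {"loci": {}}
        for name in self.loci:
            spec: dict = {"mu": self.mu[name]}
            if name in self.multicopy:
                spec["multicopy"] = True
            doc["loci"][name] = spec
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_panel() -> LocusPanel:
    """The 37-value default panel (Yfiler Plus ∪ PowerPlex Y23 + 8 singles)."""
    ref = resources.files("strclock.data").joinpath("default_panel.yaml")
    with ref.open() as fh:
        return LocusPanel._from_doc(yaml.safe_load(fh))


@dataclass
class Haplotype:
    """One sample's repeat counts over a panel, plus population metadata."""

    sample_id: str
    repeats: dict[str, object]
    population: str = ""
    district: str = ""
    ancient: bool = False
    ancient_date: str = ""
    snp_branch: str = ""

    def validate(self, panel: LocusPanel) -> list[str]:
        errors = []
        for name, val in self.repeats.items():
            if name not in panel.loci:
                errors.append(f"{self.sample_id}: unknown locus {name}")
                continue
            vals = val if isinstance(val, (tuple, list)) else (val,)
            for v in vals:
                if not float(v).is_integer() or v <= 0:
                    errors.append(f"{self.sample_id}: non-positive or fractional "
                                  f"repeat {v!r} at {name}")
        return errors


@dataclass
class HaplotypeSet:
    """A collection of haplotypes typed on a shared :class:`LocusPanel`."""

    panel: LocusPanel
    haplotypes: list[Haplotype]
    provenance: str = ""

    def __post_init__(self):
        ids = [h.sample_id for h in self.haplotypes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id: {dupes}")

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    def state_matrix(self) -> np.ndarray:
        """(n, L) float matrix of repeat values, NaN = missing."""
        return np.array([self.panel.encode(h.repeats) for h in self.haplotypes]) \
            if self.haplotypes else np.empty((0, self.panel.L))

    def subset(self, sample_ids: Iterable[str]) -> "HaplotypeSet":
        wanted = set(sample_ids)
        return replace(self, haplotypes=[h for h in self.haplotypes
                                         if h.sample_id in wanted])

    def population_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for h in self.haplotypes:
            out[h.population] = out.get(h.population, 0) + 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for h in self.haplotypes:
            row: dict[str, object] = {
                "sample_id": h.sample_id,
                "population": h.population,
                "district": h.district,
                "ancient": _format_ancient(h),
                "snp_branch": h.snp_branch,
            }
            for name in self.panel.loci:
                val = h.repeats.get(name)
                if val is None:
                    row[name] = ""
                elif isinstance(val, (tuple, list)):
                    row[name] = "-".join(str(int(v)) for v in sorted(val))
                else:
                    row[name] = str(int(val))
            rows.append(row)
        return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(self.panel.loci))

    def write(self, path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)


def _format_ancient(h: Haplotype) -> str:
    if not h.ancient:
        return ""
    return h.ancient_date or "yes"


def _parse_ancient(text: str) -> tuple[bool, str]:
    text = (text or "").strip()
    if not text or text.lower() in {"no", "false", "0", "modern"}:
        return False, ""
    if text.lower() in {"yes", "true", "1", "ancient"}:
        return True, ""
    return True, text


def _parse_allele(text: str, multicopy: bool):
    """Parse an allele cell; returns the value or None if missing/non-integer."""
    text = (text or "").strip()
    if not text or text.lower() in {"na", "nan", "none", "-", "?"}:
        return None, False
    try:
        if multicopy:
            parts = [p for p in text.split("-") if p]
            vals = tuple(sorted(int(_as_int(p)) for p in parts))
            if len(vals) != MULTICOPY_ARITY:
                return None, True
            return vals, False
        return _as_int(text), False
    except ValueError:
        return None, True


def _as_int(text: str) -> int:
    val = float(text)
    if not val.is_integer():
        raise ValueError(text)
    return int(val)


def read_haplotype_table(path, panel: LocusPanel) -> HaplotypeSet:
    """Read a delimited haplotype table (TSV or CSV, auto-detected).

    Expected header: ``sample_id, population, district, ancient, snp_branch``
    followed by locus columns matching the panel.  Non-integer alleles at a
    single-copy locus (e.g. "15.2" intermediate alleles) are treated as
    missing at that locus and logged, never rounded.  Unknown locus columns
    produce a warning and are ignored; a duplicated sample_id is an error.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")

    locus_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    unknown = [c for c in locus_cols if c not in panel.loci]
    if unknown:
        logger.warning("%s: ignoring unknown locus columns %s", path.name, unknown)
        locus_cols = [c for c in locus_cols if c in panel.loci]

    haplotypes = []
    for _, row in df.iterrows():
        repeats: dict[str, object] = {}
        for name in locus_cols:
            val, bad = _parse_allele(row[name], name in panel.multicopy)
            if bad:
                logger.warning("sample %s: non-integer allele %r at %s treated as missing",
                               row["sample_id"], row[name], name)
            if val is not None:
                repeats[name] = val
        ancient, date = _parse_ancient(row.get("ancient", ""))
        haplotypes.append(Haplotype(
            sample_id=str(row["sample_id"]),
            repeats=repeats,
            population=str(row.get("population", "")),
            district=str(row.get("district", "")),
            ancient=ancient,
            ancient_date=date,
            snp_branch=str(row.get("snp_branch", "")),
        ))
    return HaplotypeSet(panel, haplotypes, provenance=str(path))


@dataclass
class ValidationReport:
    """Report-only summary of a haplotype set; never raises."""

    n_samples: int
    per_locus_missing: dict[str, int]
    population_counts: dict[str, int]
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_set(hs: HaplotypeSet) -> ValidationReport:
    """Validate a haplotype set: missingness, population counts, invariants."""
    missing = {name: 0 for name in hs.panel.loci}
    errors: list[str] = []
    for h in hs.haplotypes:
        errors.extend(h.validate(hs.panel))
        for name in hs.panel.loci:
            if h.repeats.get(name) is None:
                missing[name] += 1
    return ValidationReport(
        n_samples=len(hs),
        per_locus_missing=missing,
        population_counts=hs.population_counts(),
        errors=errors,
    )
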