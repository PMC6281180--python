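"""Data model and I/O for temporally sampled diploid microsatellite genotypes.

The central container is :class:`GenotypeDataset`: individuals x loci diploid
allele-size calls, each individual attached to a :class:`SampleGroup` that
carries the metadata population-genetic analyses need (site, modern/ancient
status, age in calibrated years BP, seed color).  Allele calls are integer
sizes; a call is either a fully observed unordered pair or fully missing.

The canonical on-disk representation is a plain CSV with one row per
individual: the metadata columns ``individual_id, group, type, site,
age_calBP, seed_color`` followed by two columns ``<LOCUS>.a1, <LOCUS>.a2``
per locus.  Missing calls are written as ``NA`` (``-9`` and empty cells are
accepted on input).  ``read_allelic_profiles`` takes an optional
``column_map`` so files with other headers can be ingested without editing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

METADATA_COLUMNS = ("individual_id", "group", "type", "site", "age_calBP", "seed_color")

VALID_TYPES = ("modern", "ancient")
VALID_COLORS = ("white", "dark", "unknown")


class FormatError(ValueError):
    """The input file does not follow the expected layout."""


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


class EmptyDataError(ValueError):
    """An operation was asked to run on zero non-missing calls."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus scored as integer allele sizes.

    ``motif_length`` (repeat-unit length in bp) and ``size_range`` (allele
    size bounds) are optional annotations; they are not needed by the
    statistics but are carried through I/O when present.
    """

    name: str
    motif_length: int | None = None
    size_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.motif_length is not None and self.motif_length < 1:
            raise ValidationError(f"locus {self.name}: motif_length must be >= 1")


@dataclass(frozen=True)
class SampleGroup:
    """A sample of seeds from one site and one time layer."""

    label: str
    site: str = ""
    type: str = "modern"
    age_calBP: float = 0.0
    seed_color: str = "unknown"

    def __post_init__(self) -> None:
        if self.type not in VALID_TYPES:
            raise ValidationError(f"group {self.label}: type must be one of {VALID_TYPES}")
        if self.seed_color not in VALID_COLORS:
            raise ValidationError(f"group {self.label}: seed_color must be one of {VALID_COLORS}")
        if self.age_calBP < 0:
            raise ValidationError(f"group {self.label}: age_calBP must be >= 0")
        if self.type == "modern" and self.age_calBP != 0:
            raise ValidationError(f"group {self.label}: modern groups must have age_calBP == 0")


@dataclass
class ParseReport:
    """Counts of repairs applied while reading a genotype table."""

    unparseable_calls: int = 0
    half_missing_coerced: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"parse report: {self.unparseable_calls} unparseable call(s) set to missing, "
            f"{self.half_missing_coerced} half-missing genotype(s) coerced to missing"
        )


@dataclass
class GenotypeDataset:
    """Diploid SSR calls for individually labelled seeds grouped into samples.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` with integer allele
    sizes; missing calls are ``(-1, -1)``.  Allele order within a call is not
    meaningful (an unordered pair); comparisons sort the pair first.
    """

    loci: list[Locus]
    groups: list[SampleGroup]
    individual_ids: list[str]
    individual_group: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        n, L = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValidationError("locus names must be unique")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError("group labels must be unique")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dup = pd.Series(self.individual_ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise ValidationError(f"duplicated individual_id: {dup!r}")
        known = set(labels)
        for ind, grp in zip(self.individual_ids, self.individual_group):
            if grp not in known:
                raise ValidationError(f"individual {ind!r} references unknown group {grp!r}")
        a1, a2 = self.calls[..., 0], self.calls[..., 1]
        half = (a1 == MISSING) ^ (a2 == MISSING)
        if half.any():
            raise ValidationError("half-missing genotype present; calls must be fully observed or fully missing")
        observed = a1 != MISSING
        if (self.calls[observed] <= 0).any():
            raise ValidationError("allele sizes must be positive integers")

    # -- convenience -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    @property
    def group_labels(self) -> list[str]:
        return [g.label for g in self.groups]

    def group(self, label: str) -> SampleGroup:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(f"unknown group {label!r}")

    def group_rows(self, label: str) -> np.ndarray:
        """Row indices of the individuals belonging to ``label``."""
        if label not in set(self.group_labels):
            raise KeyError(f"unknown group {label!r}")
        return np.array([i for i, g in enumerate(self.individual_group) if g == label], dtype=int)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` matrix, True where the call is missing."""
        return self.calls[..., 0] == MISSING

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            loci=list(self.loci),
            groups=list(self.groups),
            individual_ids=list(self.individual_ids),
            individual_group=list(self.individual_group),
            calls=self.calls.copy(),
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        """Field-by-field equality; allele pairs compared as unordered."""
        if self.loci != other.loci or self.groups != other.groups:
            return False
        if self.individual_ids != other.individual_ids:
            return False
        if self.individual_group != other.individual_group:
            return False
        if self.calls.shape != other.calls.shape:
            return False
        return bool(np.array_equal(np.sort(self.calls, axis=2), np.sort(other.calls, axis=2)))


# ---------------------------------------------------------------------------
# I/O


def _parse_allele(value) -> int | None:
    """Integer allele size, or None for any recognized missing encoding."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    if s == "" or s.upper() in {"NA", "NAN", "-9", "0", "."}:
        return None
    try:
        x = int(float(s))
    except ValueError:
        raise FormatError(f"unparseable allele entry {value!r}")
    if x <= 0:
        return None
    return x


def read_allelic_profiles(
    path,
    column_map: Mapping[str, str] | None = None,
    return_report: bool = False,
):
    """Read a genotype CSV into a validated :class:`GenotypeDataset`.

    Parameters
    ----------
    path
        Delimited table, one row per individual: metadata columns then two
        allele columns per locus named ``<LOCUS>.a1`` / ``<LOCUS>.a2``.
    column_map
        Mapping from canonical column names (``individual_id`` etc.) to the
        actual headers of the file, for files with nonstandard layouts.
    return_report
        Also return a :class:`ParseReport` with repair counts.
    """
    df = pd.read_csv(path, dtype=str)
    cmap = dict(column_map or {})
    for canonical in METADATA_COLUMNS:
        actual = cmap.get(canonical, canonical)
        if actual not in df.columns:
            raise FormatError(f"missing mandatory metadata column: {canonical!r} (looked for {actual!r})")
        if actual != canonical:
            df = df.rename(columns={actual: canonical})

    allele_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    locus_names: list[str] = []
    for c in allele_cols:
        if not (c.endswith(".a1") or c.endswith(".a2")):
            raise FormatError(f"unexpected column {c!r}: allele columns must end in .a1/.a2")
        base = c[:-3]
        if base not in locus_names:
            locus_names.append(base)
    for base in locus_names:
        for suffix in (".a1", ".a2"):
            if base + suffix not in df.columns:
                raise FormatError(f"locus {base!r} is missing its {suffix} column")

    report = ParseReport()
    n, L = len(df), len(locus_names)
    calls = np.full((n, L, 2), MISSING, dtype=np.int32)
    for j, base in enumerate(locus_names):
        for k, suffix in enumerate((".a1", ".a2")):
            col = df[base + suffix]
            for i, raw in enumerate(col):
                try:
                    parsed = _parse_allele(raw)
                except FormatError:
                    report.unparseable_calls += 1
                    parsed = None
                calls[i, j, k] = MISSING if parsed is None else parsed
    # coerce half-missing to fully missing
    half = (calls[..., 0] == MISSING) ^ (calls[..., 1] == MISSING)
    if half.any():
        report.half_missing_coerced += int(half.sum())
        calls[half] = MISSING

    groups: list[SampleGroup] = []
    seen: dict[str, SampleGroup] = {}
    for _, row in df.iterrows():
        label = str(row["group"])
        if label not in seen:
            g = SampleGroup(
                label=label,
                site=str(row["site"]) if not pd.isna(row["site"]) else "",
                type=str(row["type"]),
                age_calBP=float(row["age_calBP"]),
                seed_color=str(row["seed_color"]) if not pd.isna(row["seed_color"]) else "unknown",
            )
            seen[label] = g
            groups.append(g)

    ds = GenotypeDataset(
        loci=[Locus(name) for name in locus_names],
        groups=groups,
        individual_ids=[str(x) for x in df["individual_id"]],
        individual_group=[str(x) for x in df["group"]],
        calls=calls,
    )
    if return_report:
        return ds, report
    return ds


def write_allelic_profiles(dataset: GenotypeDataset, path) -> None:
    """Write the canonical CSV dialect (inverse of :func:`read_allelic_profiles`)."""
    by_label = {g.label: g for g in dataset.groups}
    cols: dict[str, list] = {c: [] for c in METADATA_COLUMNS}
    for ind, grp in zip(dataset.individual_ids, dataset.individual_group):
        g = by_label[grp]
        cols["individual_id"].append(ind)
        cols["group"].append(g.label)
        cols["type"].append(g.type)
        cols["site"].append(g.site)
        cols["age_calBP"].append(g.age_calBP)
        cols["seed_color"].append(g.seed_color)
    df = pd.DataFrame(cols)
    for j, loc in enumerate(dataset.loci):
        for k, suffix in enumerate((".a1", ".a2")):
            vals = dataset.calls[:, j, k]
            df[loc.name + suffix] = ["NA" if v == MISSING else int(v) for v in vals]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Queries


def summarize_dataset(dataset: GenotypeDataset) -> dict:
    """Counts of individuals (total, by type, by group), loci, and missingness.

    Missing percentages are reported both per group and per locus, computed
    over calls (an individual x locus cell counts once).
    """
    miss = dataset.missing_mask()
    by_label = {g.label: g for g in dataset.groups}
    per_group: dict[str, dict] = {}
    for g in dataset.groups:
        rows = dataset.group_rows(g.label)
        cells = miss[rows]
        per_group[g.label] = {
            "n_individuals": int(len(rows)),
            "missing_fraction": float(cells.mean()) if cells.size else float("nan"),
        }
    per_locus = {
        loc.name: float(miss[:, j].mean()) if dataset.n_individuals else float("nan")
        for j, loc in enumerate(dataset.loci)
    }
    n_by_type = {t: 0 for t in VALID_TYPES}
    for grp in dataset.individual_group:
        n_by_type[by_label[grp].type] += 1
    return {
        "n_individuals": dataset.n_individuals,
        "n_modern": n_by_type["modern"],
        "n_ancient": n_by_type["ancient"],
        "n_loci": dataset.n_loci,
        "n_groups": len(dataset.groups),
        "per_group": per_group,
        "per_locus_missing": per_locus,
    }


def select(
    dataset: GenotypeDataset,
    groups: Iterable[str] | None = None,
    loci: Iterable[str] | None = None,
) -> GenotypeDataset:
    """Sub-dataset restricted to the given group labels and/or locus names.

    Order is preserved from the parent dataset; unknown labels raise KeyError.
    """
    if groups is None:
        keep_groups = set(dataset.group_labels)
        new_groups = list(dataset.groups)
    else:
        requested = list(groups)
        known = set(dataset.group_labels)
        for lab in requested:
            if lab not in known:
                raise KeyError(f"unknown group {lab!r}")
        keep_groups = set(requested)
        new_groups = [g for g in dataset.groups if g.label in keep_groups]

    if loci is None:
        locus_idx = list(range(dataset.n_loci))
        new_loci = list(dataset.loci)
    else:
        requested_loci = list(loci)
        name_to_idx = {loc.name: j for j, loc in enumerate(dataset.loci)}
        for name in requested_loci:
            if name not in name_to_idx:
                raise KeyError(f"unknown locus {name!r}")
        keep = set(requested_loci)
        locus_idx = [j for j, loc in enumerate(dataset.loci) if loc.name in keep]
        new_loci = [dataset.loci[j] for j in locus_idx]

    rows = [i for i, grp in enumerate(dataset.individual_group) if grp in keep_groups]
    return GenotypeDataset(
        loci=new_loci,
        groups=new_groups,
        individual_ids=[dataset.individual_ids[i] for i in rows],
        individual_group=[dataset.individual_group[i] for i in rows],
        calls=dataset.calls[np.ix_(rows, locus_idx)],
    )


def allele_frequencies(dataset: GenotypeDataset, group: str, locus: str) -> tuple[dict[int, float], int]:
    """Allele frequencies over observed gene copies in one group at one locus.

    Returns ``(frequencies, n)`` where ``n`` is the number of observed gene
    copies (2 x non-missing individuals).  Frequencies sum to 1.
    """
    rows = dataset.group_rows(group)
    try:
        j = dataset.locus_names.index(locus)
    except ValueError:
        raise KeyError(f"unknown locus {locus!r}")
    alleles = dataset.calls[rows, j, :].ravel()
    alleles = alleles[alleles != MISSING]
    if alleles.size == 0:
        raise EmptyDataError(f"group {group!r} has no observed calls at locus {locus!r}")
    values, counts = np.unique(alleles, return_counts=True)
    n = int(alleles.size)
    return {int(v): float(c) / n for v, c in zip(values, counts)}, n
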