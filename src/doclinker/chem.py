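"""Compound-class profiling of formula-assigned FTICR-MS peak lists.

Ultrahigh-resolution FTICR-MS peaks that have been assigned an exact
molecular formula (C/H/O/N/S/P counts) can be placed on a van Krevelen
diagram — H:C molar ratio against O:C molar ratio — where rectangular
regions correspond to putative biochemical compound classes (lipid-like,
protein-like, tannin-like, ...). This module turns per-sample,
per-extraction-solvent peak lists into per-sample compound-class count
profiles:

1. classify every assigned formula by its (O:C, H:C) position,
2. merge the three sequential extractions (water, methanol, chloroform)
   of one sample into a set of distinct formulas, so a compound detected
   in more than one solvent is counted once,
3. normalize class peak counts by the lignin-like count (lignin enters
   the system only with the plant litter substrate and acts as an
   internal control for electrospray charge-competition artifacts),
4. log-transform, scale and center profiles for ordination and
   correlation analysis.

Counts are peak counts, never summed intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_BOUNDARIES",
    "MolecularFormula",
    "FticrSample",
    "BoundaryTable",
    "elemental_ratios",
    "assign_compound_class",
    "assign_classes",
    "merge_extractions",
    "class_count_profile",
    "lignin_normalize",
    "profile_matrix",
    "normalize_profiles",
    "transform_profiles",
    "ProfileTransformer",
]

#: The nine-class vocabulary, in reporting order.
CLASS_NAMES = (
    "amino sugar",
    "carbohydrate",
    "condensed hydrocarbon",
    "lignin",
    "lipid",
    "protein",
    "tannin",
    "unsaturated hydrocarbon",
    "unclassified",
)

ELEMENT_COLUMNS = ["C", "H", "O", "N", "S", "P"]


class MolecularFormula(NamedTuple):
    """Element counts of one assigned FTICR peak.

    Equality on all six counts is the de-duplication key used when
    merging extractions.
    """

    c: int
    h: int
    o: int = 0
    n: int = 0
    s: int = 0
    p: int = 0


@dataclass
class FticrSample:
    """One sample's formula-assigned peak lists, keyed by extraction solvent.

    Each peak list is a DataFrame with columns ``mz``, ``intensity`` and
    the element-count columns C/H/O/N/S/P. Rows with missing element
    counts represent peaks Formularity could not assign; they are
    excluded from class profiling.
    """

    sample_id: str
    peak_lists: dict[str, pd.DataFrame] = field(default_factory=dict)

    def merged_formulas(self) -> pd.DataFrame:
        return merge_extractions(list(self.peak_lists.values()))


class BoundaryTable:
    """Ordered van Krevelen class regions with first-match-wins lookup.

    Each region is ``(class name, [oc_low, oc_high), [hc_low, hc_high))``
    with half-open intervals; a point matching no region is
    ``unclassified``. The default table is data, not code: it can be
    overridden from a YAML/CSV config (see :func:`BoundaryTable.from_records`).
    """

    def __init__(self, regions: Sequence[tuple[str, tuple[float, float], tuple[float, float]]]):
        for name, _, _ in regions:
            if name not in CLASS_NAMES:
                raise ValueError(f"unknown compound class {name!r}")
        self.regions = list(regions)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "BoundaryTable":
        """Build from dicts with keys class, oc_low, oc_high, hc_low, hc_high."""
        regions = [
            (r["class"], (float(r["oc_low"]), float(r["oc_high"])), (float(r["hc_low"]), float(r["hc_high"])))
            for r in records
        ]
        return cls(regions)

    def to_records(self) -> list[dict]:
        return [
            {"class": name, "oc_low": oc[0], "oc_high": oc[1], "hc_low": hc[0], "hc_high": hc[1]}
            for name, oc, hc in self.regions
        ]

    def lookup(self, oc: float, hc: float) -> str:
        for name, (oc_lo, oc_hi), (hc_lo, hc_hi) in self.regions:
            if oc_lo <= oc < oc_hi and hc_lo <= hc < hc_hi:
                return name
        return "unclassified"


# Rectangular van Krevelen regions; evaluation order is fixed and the
# first matching region wins, so overlapping corners cannot double-assign.
DEFAULT_BOUNDARIES = BoundaryTable(
    [
        ("lipid", (0.0, 0.3), (1.5, 2.5)),
        ("protein", (0.3, 0.55), (1.5, 2.3)),
        ("amino sugar", (0.55, 0.7), (1.5, 2.2)),
        ("carbohydrate", (0.7, 1.5), (1.5, 2.5)),
        ("unsaturated hydrocarbon", (0.0, 0.125), (0.8, 1.5)),
        ("lignin", (0.125, 0.65), (0.8, 1.5)),
        ("tannin", (0.65, 1.1), (0.8, 1.5)),
        ("condensed hydrocarbon", (0.0, 0.95), (0.2, 0.8)),
    ]
)


def elemental_ratios(formula: MolecularFormula) -> tuple[float, float]:
    """Return the (O:C, H:C) molar ratios of a formula.

    Raises ValueError when the carbon count is zero (ratios undefined).
    """
    if formula.c < 1:
        raise ValueError(f"O:C and H:C undefined for carbon count {formula.c}")
    return formula.o / formula.c, formula.h / formula.c


def assign_compound_class(formula: MolecularFormula, boundaries: BoundaryTable | None = None) -> str:
    """Assign one formula to a compound class by its van Krevelen position."""
    boundaries = boundaries or DEFAULT_BOUNDARIES
    oc, hc = elemental_ratios(formula)
    return boundaries.lookup(oc, hc)


def assign_classes(oc: np.ndarray, hc: np.ndarray, boundaries: BoundaryTable | None = None) -> np.ndarray:
    """Vectorized class assignment for arrays of O:C and H:C ratios."""
    boundaries = boundaries or DEFAULT_BOUNDARIES
    oc = np.asarray(oc, dtype=float)
    hc = np.asarray(hc, dtype=float)
    out = np.full(oc.shape, "unclassified", dtype=object)
    unassigned = np.ones(oc.shape, dtype=bool)
    for name, (oc_lo, oc_hi), (hc_lo, hc_hi) in boundaries.regions:
        hit = unassigned & (oc >= oc_lo) & (oc < oc_hi) & (hc >= hc_lo) & (hc < hc_hi)
        out[hit] = name
        unassigned &= ~hit
    return out


def _formula_frame(peaks: pd.DataFrame) -> pd.DataFrame:
    """Keep assigned peaks only and coerce element counts to integers."""
    cols = [c for c in ELEMENT_COLUMNS if c in peaks.columns]
    if len(cols) < 2 or "C" not in cols or "H" not in cols:
        raise ValueError("peak list needs at least C and H element columns")
    sub = peaks[cols].apply(pd.to_numeric, errors="coerce")
    sub = sub.reindex(columns=ELEMENT_COLUMNS, fill_value=0)
    sub = sub.dropna(subset=["C", "H"]).fillna(0)
    sub = sub[sub["C"] >= 1]
    return sub.astype(int)


def merge_extractions(peak_lists: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Union of assigned formulas across extraction solvents.

    The key is the full six-element count vector: a formula detected in
    several solvents contributes exactly one row. Unassigned peaks
    (missing element counts) are dropped. Returns a DataFrame with
    columns C/H/O/N/S/P, one row per distinct formula, sorted for
    determinism.
    """
    if len(peak_lists) == 0:
        raise ValueError("need at least one peak list")
    frames = [_formula_frame(p) for p in peak_lists if len(p)]
    if not frames:
        return pd.DataFrame(columns=ELEMENT_COLUMNS, dtype=int)
    merged = pd.concat(frames, ignore_index=True).drop_duplicates()
    return merged.sort_values(ELEMENT_COLUMNS, kind="mergesort").reset_index(drop=True)


def class_count_profile(
    sample: FticrSample | pd.DataFrame,
    boundaries: BoundaryTable | None = None,
) -> pd.Series:
    """Count distinct assigned formulas per compound class for one sample.

    Accepts either an :class:`FticrSample` (extractions are merged first)
    or an already-merged formula DataFrame. The result is a Series over
    the nine class names; its sum equals the number of distinct formulas.
    """
    merged = sample.merged_formulas() if isinstance(sample, FticrSample) else merge_extractions([sample])
    if len(merged) == 0:
        raise ValueError("no assigned formulas in sample after merging")
    oc = merged["O"].to_numpy() / merged["C"].to_numpy()
    hc = merged["H"].to_numpy() / merged["C"].to_numpy()
    classes = assign_classes(oc, hc, boundaries)
    counts = pd.Series(0, index=list(CLASS_NAMES), dtype=int)
    vc = pd.Series(classes).value_counts()
    counts[vc.index] = vc.to_numpy()
    return counts


def lignin_normalize(raw_counts: pd.Series) -> pd.Series:
    """Divide every class count by the lignin count (internal control).

    Lignin-like peak detection tracks electrospray crowding rather than
    lignin input, so the ratio removes the per-sample ionization
    artifact. A sample with zero lignin peaks cannot be normalized and
    raises ValueError; callers flag and exclude it.
    """
    lignin = raw_counts["lignin"]
    if lignin <= 0:
        raise ValueError("lignin count is zero; sample cannot be lignin-normalized")
    return raw_counts / float(lignin)


def profile_matrix(
    samples: Sequence[FticrSample],
    boundaries: BoundaryTable | None = None,
) -> pd.DataFrame:
    """Raw samples x classes count matrix from a list of FTICR samples."""
    rows = {s.sample_id: class_count_profile(s, boundaries) for s in samples}
    return pd.DataFrame.from_dict(rows, orient="index")[list(CLASS_NAMES)]


def normalize_profiles(raw: pd.DataFrame) -> pd.DataFrame:
    """Lignin-normalize each row; zero-lignin samples are dropped with a warning."""
    keep = raw["lignin"] > 0
    if not keep.all():
        dropped = list(raw.index[~keep])
        warnings.warn(
            f"excluding {len(dropped)} sample(s) with zero lignin peaks: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    sub = raw.loc[keep]
    return sub.div(sub["lignin"].astype(float), axis=0)


class ProfileTransformer(TransformerMixin, BaseEstimator):
    """Log-transform, scale to unit variance and mean-center class profiles.

    The fixed order is log(x + pseudocount), then per-class
    standardization (which includes centering). Columns that are
    constant after the log step cannot be scaled; they are centered
    only (yielding zeros) and a warning is issued.

    Parameters
    ----------
    pseudocount : float, default 1.0
        Added before the log so zero counts stay finite.
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = self._validate(X)
        logged = np.log(X + self.pseudocount)
        self.mean_ = logged.mean(axis=0)
        self.scale_ = logged.std(axis=0, ddof=0)
        self.constant_mask_ = self.scale_ == 0
        if self.constant_mask_.any():
            warnings.warn(
                f"{int(self.constant_mask_.sum())} constant class column(s); centered but not scaled",
                UserWarning,
                stacklevel=2,
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        columns = X.columns if isinstance(X, pd.DataFrame) else None
        index = X.index if isinstance(X, pd.DataFrame) else None
        arr = self._validate(X)
        logged = np.log(arr + self.pseudocount)
        scale = np.where(self.constant_mask_, 1.0, self.scale_)
        out = (logged - self.mean_) / scale
        if columns is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out

    @staticmethod
    def _validate(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D samples x classes matrix")
        if (arr < 0).any():
            raise ValueError("class profiles must be non-negative")
        return arr


def transform_profiles(profiles: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Functional wrapper: fit a :class:`ProfileTransformer` and transform."""
    return ProfileTransformer(pseudocount=pseudocount).fit_transform(profiles)
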