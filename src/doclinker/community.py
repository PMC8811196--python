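"""OTU-table preparation: taxonomy-confidence filtering and rarefaction.

OTU tables arrive as integer samples x OTUs count matrices together
with per-rank RDP-classifier taxonomy labels and confidence
percentages. Two preparation steps precede any analysis:

* retention rules on classifier confidence — an OTU must be classified
  to its kingdom (bacteria or fungi) with 100% confidence and to a
  phylum with at least 80%; below the phylum, labels need at least 70%
  confidence to be usable, and the *effective rank* of an OTU is the
  deepest rank whose label (and all shallower labels) pass. Sub-cutoff
  labels are retained for display but flagged unusable.
* rarefaction — every sample is subsampled without replacement
  (multivariate hypergeometric) to a fixed depth so library-size
  differences cannot masquerade as community differences. Samples with
  fewer reads than the depth are dropped with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RANKS",
    "CONFIDENCE_THRESHOLDS",
    "effective_rank",
    "annotate_taxonomy",
    "filter_by_confidence",
    "rarefy",
    "Rarefier",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Minimum classifier confidence (percent) for a rank label to be usable.
CONFIDENCE_THRESHOLDS = {
    "kingdom": 100.0,
    "phylum": 80.0,
    "class": 70.0,
    "order": 70.0,
    "family": 70.0,
    "genus": 70.0,
}


def _conf_col(rank: str) -> str:
    return f"{rank}_conf"


def effective_rank(confidences: pd.Series) -> str | None:
    """Deepest rank whose confidence, and all shallower confidences, pass.

    Returns None when even the kingdom assignment fails (OTU is removed
    downstream). Mirrors the reporting convention where sub-cutoff
    scores are shown in parentheses but never used: an OTU with family
    90% and genus 67% resolves to family.
    """
    deepest = None
    for rank in RANKS:
        conf = confidences.get(_conf_col(rank), np.nan)
        if pd.isna(conf) or conf < CONFIDENCE_THRESHOLDS[rank]:
            break
        deepest = rank
    return deepest


def annotate_taxonomy(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Add ``effective_rank`` and ``retained`` columns to a taxonomy table.

    Expects one row per OTU (index = OTU id) with columns
    ``kingdom..genus`` and ``kingdom_conf..genus_conf`` (percent).
    ``retained`` requires kingdom at 100% and phylum at >=80%.
    """
    missing = [c for c in ("kingdom_conf", "phylum_conf") if c not in taxonomy.columns]
    if missing:
        raise ValueError(f"taxonomy table lacks confidence columns {missing}")
    out = taxonomy.copy()
    out["effective_rank"] = [effective_rank(row) for _, row in taxonomy.iterrows()]
    out["retained"] = (
        (taxonomy["kingdom_conf"] >= CONFIDENCE_THRESHOLDS["kingdom"])
        & (taxonomy["phylum_conf"] >= CONFIDENCE_THRESHOLDS["phylum"])
    )
    # Labels below the effective rank stay visible for audit but are
    # blanked in the usable-label columns.
    for i, rank in enumerate(RANKS):
        usable = []
        for otu, row in out.iterrows():
            eff = row["effective_rank"]
            ok = eff is not None and RANKS.index(eff) >= i
            usable.append(row.get(rank) if ok else None)
        out[f"{rank}_usable"] = usable
    return out


def filter_by_confidence(
    counts: pd.DataFrame, taxonomy: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop OTUs failing the kingdom/phylum confidence retention rules.

    ``counts`` is samples x OTUs; every OTU column must have a taxonomy
    row. Returns the filtered count table and the annotated taxonomy of
    the surviving OTUs.
    """
    missing = [o for o in counts.columns if o not in taxonomy.index]
    if missing:
        raise KeyError(f"OTUs without a taxonomy row: {missing[:5]}" + ("..." if len(missing) > 5 else ""))
    annotated = annotate_taxonomy(taxonomy.loc[list(counts.columns)])
    keep = annotated.index[annotated["retained"]]
    return counts[list(keep)], annotated.loc[keep]


def rarefy(
    counts: pd.DataFrame, depth: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained row is a multivariate-hypergeometric draw from the
    sample's observed counts, so row sums equal ``depth`` exactly and no
    count ever increases. Samples with fewer than ``depth`` total reads
    are dropped with a warning. Deterministic given the seed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    shallow = list(counts.index[totals < depth])
    if shallow:
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below rarefaction depth {depth}: {shallow[:5]}",
            UserWarning,
            stacklevel=2,
        )
    kept = counts.loc[totals >= depth]
    rows = np.empty(kept.shape, dtype=np.int64)
    for i, (_, row) in enumerate(kept.iterrows()):
        rows[i] = rng.multivariate_hypergeometric(row.to_numpy(dtype=np.int64), depth)
    return pd.DataFrame(rows, index=kept.index, columns=kept.columns)


class Rarefier(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`rarefy` for pipeline composition."""

    def __init__(self, depth: int = 1023, random_state: int | None = 0):
        self.depth = depth
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        return self

    def transform(self, X):
        return rarefy(X, self.depth, np.random.default_rng(self.random_state))
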