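"""Synthetic microcosm studies with planted, recoverable structure.

The generator emulates the statistical shape of a litter-decomposition
microcosm experiment relating soil microbial communities and DOC
chemistry, so that every downstream stage can be verified by parameter
recovery:

* per-sample DOC concentrations from a two-component (low/high) normal
  mixture — the bimodal extreme-cohort design;
* per-sample FTICR peak lists whose compound-class counts covary with
  DOC (protein-like positively, tannin-like negatively, configurable
  per class), with formulas drawn inside each class's van Krevelen
  region so downstream classification is consistent by construction;
* a lignin internal control: the *true* lignin input is constant
  across samples, but the *detected* lignin count is inflated by a
  charge-competition (crowding) factor that grows as other compounds
  thin out, so raw lignin detection anti-correlates with DOC;
* three extraction-solvent peak lists per sample with partial overlap,
  to exercise formula de-duplication;
* overdispersed OTU count tables (gamma-heterogeneity multinomial,
  i.e. log-linear expected abundance in standardized DOC with
  negative-binomial-like dispersion) containing a small set of planted
  DOC-associated taxa among many null taxa, plus RDP-style taxonomy
  tables with configurable sub-threshold confidence fractions;
* the ground truth (planted taxa and directions, class–DOC signs,
  cohort labels) for scoring recovery.

Everything is driven by one seeded generator: identical config + seed
gives bitwise-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import CLASS_NAMES, DEFAULT_BOUNDARIES, BoundaryTable, FticrSample

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_dataset",
    "generate_taxonomy",
]

# Expected peak counts per compound class at mean DOC, and their slopes
# on standardized DOC. Protein-like compounds rise with DOC, tannin- and
# hydrocarbon-like compounds fall; carbohydrates are neutral.
DEFAULT_CLASS_BASE = {
    "protein": 60,
    "lipid": 40,
    "amino sugar": 25,
    "carbohydrate": 50,
    "tannin": 60,
    "condensed hydrocarbon": 40,
    "unsaturated hydrocarbon": 30,
    "unclassified": 50,
}
# Net total load rises with DOC (sum of slopes > 0): charge competition
# is driven by how much co-ionizing material a sample carries, so the
# lignin crowding artifact only emerges when high-DOC samples are
# peak-richer overall.
DEFAULT_CLASS_EFFECT = {
    "protein": 35.0,
    "lipid": 18.0,
    "amino sugar": 10.0,
    "carbohydrate": 0.0,
    "tannin": -12.0,
    "condensed hydrocarbon": -6.0,
    "unsaturated hydrocarbon": -4.0,
    "unclassified": -3.0,
}

SOLVENTS = ("water", "methanol", "chloroform")

# Monoisotopic masses for m/z synthesis.
_MASS = {"C": 12.0, "H": 1.007825, "O": 15.994915, "N": 14.003074, "S": 31.972071, "P": 30.973762}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the scale of the real design: 125 samples split
    into high/low DOC cohorts, a few hundred bacterial OTUs with ten
    planted DOC-associated taxa, and class-count slopes giving strong
    positive protein and negative tannin correlations with DOC.
    """

    n_samples: int = 125
    n_otus_bacteria: int = 500
    n_otus_fungi: int = 150
    n_planted_positive: int = 5
    n_planted_negative: int = 5
    doc_low_mean: float = 8.0  # mg C/L
    doc_high_mean: float = 45.0  # mg C/L
    doc_sd: float = 6.0  # mg C/L
    class_base: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_BASE))
    class_effect: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_EFFECT))
    lignin_base_count: int = 80
    crowding_strength: float = 1.0
    planted_effect: float = 1.0  # log-abundance slope per DOC SD
    otu_dispersion: float = 0.3
    library_size_range: tuple[int, int] = (2500, 6000)
    extraction_overlap: float = 0.2
    frac_subthreshold_kingdom: float = 0.05
    frac_subthreshold_phylum: float = 0.05
    frac_subthreshold_lower: float = 0.15
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("SyntheticConfig.seed is required for reproducibility")
        if self.n_planted_positive + self.n_planted_negative >= self.n_otus_bacteria:
            raise ValueError("planted taxa must be fewer than bacterial OTUs")
        if not (0 < self.doc_low_mean < self.doc_high_mean):
            raise ValueError("need 0 < doc_low_mean < doc_high_mean")
        if self.crowding_strength < 0:
            raise ValueError("crowding_strength must be >= 0")
        if self.otu_dispersion <= 0:
            raise ValueError("otu_dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid library_size_range")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    planted_taxa: dict  # OTU id -> +1 / -1
    class_doc_signs: dict  # class -> expected correlation sign with DOC
    cohort_labels: dict  # sample id -> "high" | "low"


@dataclass
class SyntheticStudy:
    """One generated study: all inputs the pipeline consumes, plus truth."""

    config: SyntheticConfig
    doc: pd.Series
    bacteria_counts: pd.DataFrame
    fungi_counts: pd.DataFrame
    bacteria_taxonomy: pd.DataFrame
    fungi_taxonomy: pd.DataFrame
    fticr_samples: list
    class_counts_true: pd.DataFrame  # planted per-class counts incl. detected lignin
    truth: GroundTruth


def _formula_pool(
    cls: str, size: int, rng: np.random.Generator, boundaries: BoundaryTable
) -> np.ndarray:
    """Distinct formulas (rows C,H,O,N,S,P) classified as ``cls``.

    Samples target (O:C, H:C) points inside the class region (or, for
    ``unclassified``, in a gap outside every region), draws a carbon
    count and rounds O and H; rounding can move a point across a
    boundary, so each candidate is re-checked against the table.
    """
    if cls == "unclassified":
        oc_lo, oc_hi, hc_lo, hc_hi = 1.6, 2.4, 0.25, 0.75
    else:
        region = next(r for r in boundaries.regions if r[0] == cls)
        (oc_lo, oc_hi), (hc_lo, hc_hi) = region[1], region[2]
    pool: set[tuple] = set()
    attempts = 0
    while len(pool) < size and attempts < 200:
        attempts += 1
        m = size * 2
        c = rng.integers(8, 35, size=m)
        oc = rng.uniform(oc_lo, oc_hi, size=m)
        hc = rng.uniform(hc_lo, hc_hi, size=m)
        o = np.rint(oc * c).astype(int)
        h = np.maximum(np.rint(hc * c).astype(int), 1)
        n = rng.integers(0, 3, size=m)
        s = (rng.random(m) < 0.1).astype(int)
        p = (rng.random(m) < 0.05).astype(int)
        ok = np.array(
            [boundaries.lookup(o[i] / c[i], h[i] / c[i]) == cls for i in range(m)]
        )
        for i in np.flatnonzero(ok):
            pool.add((int(c[i]), int(h[i]), int(o[i]), int(n[i]), int(s[i]), int(p[i])))
            if len(pool) >= size:
                break
    return np.array(sorted(pool), dtype=int)


def _split_extractions(
    formulas: np.ndarray, rng: np.random.Generator, overlap: float
) -> dict[str, np.ndarray]:
    """Assign each formula a primary solvent, plus a second one w.p. overlap."""
    primary = rng.integers(0, 3, size=len(formulas))
    second = (primary + 1 + rng.integers(0, 2, size=len(formulas))) % 3
    has_second = rng.random(len(formulas)) < overlap
    lists: dict[str, list] = {s: [] for s in SOLVENTS}
    for i, row in enumerate(formulas):
        lists[SOLVENTS[primary[i]]].append(row)
        if has_second[i]:
            lists[SOLVENTS[second[i]]].append(row)
    return {s: np.array(v, dtype=int).reshape(-1, 6) for s, v in lists.items()}


def _peak_frame(formulas: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    mass = (
        formulas[:, 0] * _MASS["C"]
        + formulas[:, 1] * _MASS["H"]
        + formulas[:, 2] * _MASS["O"]
        + formulas[:, 3] * _MASS["N"]
        + formulas[:, 4] * _MASS["S"]
        + formulas[:, 5] * _MASS["P"]
    )
    return pd.DataFrame(
        {
            "mz": np.round(mass - _MASS["H"], 6),  # [M-H]- style
            "intensity": np.round(rng.lognormal(mean=10.0, sigma=1.0, size=len(formulas)), 3),
            "C": formulas[:, 0],
            "H": formulas[:, 1],
            "O": formulas[:, 2],
            "N": formulas[:, 3],
            "S": formulas[:, 4],
            "P": formulas[:, 5],
        }
    )


_PHYLA_B = ["Proteobacteria", "Actinobacteria", "Bacteroidetes", "Firmicutes", "Verrucomicrobia", "Planctomycetes"]
_PHYLA_F = ["Ascomycota", "Basidiomycota", "Mucoromycota"]


def generate_taxonomy(
    otu_ids,
    kingdom: str,
    seed: int | np.random.Generator,
    frac_subthreshold_kingdom: float = 0.05,
    frac_subthreshold_phylum: float = 0.05,
    frac_subthreshold_lower: float = 0.15,
    protected=(),
) -> pd.DataFrame:
    """RDP-style taxonomy with per-rank labels and confidence percentages.

    A configurable fraction of OTUs receives sub-threshold confidences
    at the kingdom (<100%), phylum (<80%) or a lower rank (<70%) so the
    downstream retention filter has work to do. OTUs in ``protected``
    always get passing confidences at every rank.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    otu_ids = list(otu_ids)
    n = len(otu_ids)
    phyla = _PHYLA_B if kingdom.lower().startswith("bact") else _PHYLA_F
    protected = set(protected)

    u = rng.random(n)
    sub_k = u < frac_subthreshold_kingdom
    sub_p = (u >= frac_subthreshold_kingdom) & (u < frac_subthreshold_kingdom + frac_subthreshold_phylum)
    sub_l = (
        (u >= frac_subthreshold_kingdom + frac_subthreshold_phylum)
        & (u < frac_subthreshold_kingdom + frac_subthreshold_phylum + frac_subthreshold_lower)
    )
    rows = []
    for i, otu in enumerate(otu_ids):
        prot = otu in protected
        row = {
            "kingdom": kingdom,
            "phylum": phyla[int(rng.integers(len(phyla)))],
            "class": f"Class_{int(rng.integers(1, 15)):02d}",
            "order": f"Order_{int(rng.integers(1, 25)):02d}",
            "family": f"Family_{int(rng.integers(1, 40)):02d}",
            "genus": f"Genus_{int(rng.integers(1, 80)):02d}",
        }
        row["kingdom_conf"] = 100
        row["phylum_conf"] = int(rng.integers(85, 101))
        for r in ("class", "order", "family", "genus"):
            row[f"{r}_conf"] = int(rng.integers(75, 101))
        if not prot:
            if sub_k[i]:
                row["kingdom_conf"] = int(rng.integers(80, 100))
            elif sub_p[i]:
                row["phylum_conf"] = int(rng.integers(50, 80))
            elif sub_l[i]:
                rank = ("class", "order", "family", "genus")[int(rng.integers(4))]
                row[f"{rank}_conf"] = int(rng.integers(20, 70))
        rows.append(row)
    df = pd.DataFrame(rows, index=otu_ids)
    df.index.name = "otu_id"
    return df


def _otu_table(
    rng: np.random.Generator,
    sample_ids,
    n_otus: int,
    prefix: str,
    z: np.ndarray,
    planted: dict[str, int],
    planted_effect: float,
    dispersion: float,
    library_range: tuple[int, int],
) -> pd.DataFrame:
    otu_ids = [f"{prefix}{i + 1}" for i in range(n_otus)]
    base = rng.normal(0.0, 1.2, size=n_otus)
    beta = np.zeros(n_otus)
    for otu, direction in planted.items():
        j = otu_ids.index(otu)
        base[j] = rng.normal(1.5, 0.3)  # planted taxa are reasonably abundant
        beta[j] = direction * planted_effect
    log_mu = base[None, :] + z[:, None] * beta[None, :]
    shape = 1.0 / dispersion
    gamma = rng.gamma(shape, scale=1.0 / shape, size=log_mu.shape)
    weights = np.exp(log_mu) * gamma
    libs = rng.integers(library_range[0], library_range[1] + 1, size=len(sample_ids))
    counts = np.vstack(
        [rng.multinomial(libs[i], weights[i] / weights[i].sum()) for i in range(len(sample_ids))]
    )
    return pd.DataFrame(counts, index=sample_ids, columns=otu_ids)


def generate_dataset(config: SyntheticConfig) -> SyntheticStudy:
    """Generate one full synthetic study. See the module docstring."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    # --- DOC: two-component mixture, low cohort gets the extra sample ---
    n_low = int(np.ceil(n / 2))
    comps = np.array(["low"] * n_low + ["high"] * (n - n_low))
    rng.shuffle(comps)
    doc_vals = np.where(
        comps == "low",
        rng.normal(config.doc_low_mean, config.doc_sd, size=n),
        rng.normal(config.doc_high_mean, config.doc_sd, size=n),
    )
    doc_vals = np.clip(doc_vals, 0.5, None)
    doc = pd.Series(doc_vals, index=sample_ids, name="doc")
    z = (doc_vals - doc_vals.mean()) / doc_vals.std()

    # cohorts: bottom ceil(n/2) by DOC are "low", rest "high"
    order = np.argsort(doc_vals, kind="mergesort")
    cohort = np.full(n, "high", dtype=object)
    cohort[order[:n_low]] = "low"
    cohort_labels = dict(zip(sample_ids, cohort))

    # --- planted class counts ---
    class_counts = pd.DataFrame(0, index=sample_ids, columns=list(CLASS_NAMES), dtype=int)
    clamped = 0
    for cls in CLASS_NAMES:
        if cls == "lignin":
            continue
        base = config.class_base.get(cls, 0)
        slope = config.class_effect.get(cls, 0.0)
        lam = base + slope * z
        neg = lam < 0
        clamped += int(neg.sum())
        lam = np.clip(lam, 0.0, None)
        class_counts[cls] = rng.poisson(lam)
    if clamped:
        warnings.warn(
            f"{clamped} expected class counts were negative and clamped to 0",
            UserWarning,
            stacklevel=2,
        )
    true_lignin = rng.poisson(config.lignin_base_count, size=n)
    nonlignin_total = class_counts.drop(columns="lignin").sum(axis=1).to_numpy()
    ref_total = float(sum(config.class_base.values()))
    inflation = 1.0 + config.crowding_strength * ref_total / np.maximum(nonlignin_total, 1)
    class_counts["lignin"] = np.rint(true_lignin * inflation).astype(int)

    # --- FTICR peak lists ---
    boundaries = DEFAULT_BOUNDARIES
    pools = {}
    for cls in CLASS_NAMES:
        need = int(class_counts[cls].max() * 1.2) + 10
        pools[cls] = _formula_pool(cls, need, rng, boundaries)
    fticr_samples = []
    for i, sid in enumerate(sample_ids):
        chunks = []
        for cls in CLASS_NAMES:
            k = int(class_counts.loc[sid, cls])
            pool = pools[cls]
            if k > len(pool):  # pool exhausted; cap (rare, logged)
                warnings.warn(f"formula pool for {cls} capped at {len(pool)}", UserWarning)
                k = len(pool)
                class_counts.loc[sid, cls] = k
            if k:
                idx = rng.choice(len(pool), size=k, replace=False)
                chunks.append(pool[idx])
        formulas = np.vstack(chunks)
        solvent_lists = _split_extractions(formulas, rng, config.extraction_overlap)
        peak_lists = {s: _peak_frame(v, rng) for s, v in solvent_lists.items() if len(v)}
        fticr_samples.append(FticrSample(sample_id=sid, peak_lists=peak_lists))

    # --- OTU tables ---
    planted_ids_pos = [f"B_OTU_{i + 1}" for i in range(config.n_planted_positive)]
    planted_ids_neg = [
        f"B_OTU_{i + 1 + config.n_planted_positive}" for i in range(config.n_planted_negative)
    ]
    planted = {**{o: 1 for o in planted_ids_pos}, **{o: -1 for o in planted_ids_neg}}
    bacteria = _otu_table(
        rng, sample_ids, config.n_otus_bacteria, "B_OTU_", z, planted,
        config.planted_effect, config.otu_dispersion, config.library_size_range,
    )
    fungi = _otu_table(
        rng, sample_ids, config.n_otus_fungi, "F_OTU_", z, {},
        config.planted_effect, config.otu_dispersion, config.library_size_range,
    )
    tax_b = generate_taxonomy(
        bacteria.columns, "Bacteria", rng,
        config.frac_subthreshold_kingdom, config.frac_subthreshold_phylum,
        config.frac_subthreshold_lower, protected=planted,
    )
    tax_f = generate_taxonomy(
        fungi.columns, "Fungi", rng,
        config.frac_subthreshold_kingdom, config.frac_subthreshold_phylum,
        config.frac_subthreshold_lower,
    )

    class_signs = {
        cls: int(np.sign(config.class_effect.get(cls, 0.0))) for cls in CLASS_NAMES if cls != "lignin"
    }
    class_signs["lignin"] = -1 if config.crowding_strength > 0 else 0
    truth = GroundTruth(
        planted_taxa=planted, class_doc_signs=class_signs, cohort_labels=cohort_labels
    )
    return SyntheticStudy(
        config=config,
        doc=doc,
        bacteria_counts=bacteria,
        fungi_counts=fungi,
        bacteria_taxonomy=tax_b,
        fungi_taxonomy=tax_f,
        fticr_samples=fticr_samples,
        class_counts_true=class_counts,
        truth=truth,
    )
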