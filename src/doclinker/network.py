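"""Taxa–compound–DOC correlation network and consistency check.

Edges are Spearman correlations among (i) the consensus taxa's
abundances, (ii) the lignin-normalized compound-class counts and
(iii) DOC concentration, kept when p < alpha (raw p by default, to
mirror the per-class reporting convention; Benjamini–Hochberg is
available). The consistency check asks, for each taxon with a
significant edge to a focus class (protein by default), whether the
sign chain

    sign(rho(taxon, class)) × sign(rho(class, DOC))

agrees with the taxon's indicator-species cohort: +1 for high-DOC
indicators, −1 for low-DOC indicators. A low-DOC taxon negatively
correlated with a class that itself rises with DOC is consistent.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .stats import spearman

__all__ = [
    "build_edges",
    "consistency_check",
    "to_graph",
    "write_sif",
    "write_edge_attributes",
]

DOC_NODE = "DOC"


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def build_edges(
    taxa: pd.DataFrame,
    classes: pd.DataFrame,
    doc,
    alpha: float = 0.05,
    p_adjust: str | None = None,
) -> pd.DataFrame:
    """Spearman edges among taxa, compound classes and DOC.

    ``taxa`` (samples x consensus taxa) and ``classes`` (samples x
    classes) must share the sample order of ``doc``. All taxon–class,
    taxon–DOC and class–DOC pairs are tested; edges with p < ``alpha``
    are kept (after Benjamini–Hochberg when ``p_adjust='bh'``). An
    empty taxa table yields the class–DOC edges only. Returns a
    DataFrame with columns source, target, rho, p, sign.
    """
    doc = np.asarray(doc, dtype=float)
    if len(taxa) and len(taxa) != len(doc):
        raise ValueError("taxa table and DOC vector lengths differ")
    if len(classes) != len(doc):
        raise ValueError("class table and DOC vector lengths differ")
    vectors: dict[str, np.ndarray] = {DOC_NODE: doc}
    taxon_names = [str(t) for t in taxa.columns]
    class_names = [str(c) for c in classes.columns]
    for t in taxa.columns:
        vectors[str(t)] = taxa[t].to_numpy(dtype=float)
    for c in classes.columns:
        vectors[str(c)] = classes[c].to_numpy(dtype=float)

    pairs: list[tuple[str, str]] = []
    pairs += [(t, c) for t in taxon_names for c in class_names]
    pairs += [(t, DOC_NODE) for t in taxon_names]
    pairs += [(c, DOC_NODE) for c in class_names]

    rows = []
    for src, tgt in pairs:
        try:
            res = spearman(vectors[src], vectors[tgt])
        except ValueError:  # constant vector: no information, no edge
            continue
        rows.append({"source": src, "target": tgt, "rho": res.rho, "p": res.p})
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p"])
    if len(edges) == 0:
        edges["sign"] = pd.Series(dtype=object)
        return edges
    if p_adjust == "bh":
        edges["p"] = _bh_adjust(edges["p"].to_numpy())
    elif p_adjust is not None:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    edges = edges[edges["p"] < alpha].reset_index(drop=True)
    edges["sign"] = np.where(edges["rho"] >= 0, "+", "-")
    return edges


def consistency_check(
    edges: pd.DataFrame,
    indval_groups: pd.Series | dict,
    focus_class: str = "protein",
) -> pd.DataFrame:
    """Verdict per taxon: does its cohort match its correlation signs?

    For every taxon with a retained edge to ``focus_class``, the rule is

        consistent  <=>  sign(rho(taxon, class)) * sign(rho(class, DOC))
                          == (+1 if cohort == high else -1)

    Taxa without a focus-class edge are skipped. Returns a DataFrame
    with one row per checked taxon (indval_group, rho_with_class,
    class_rho_with_doc, consistent).
    """
    groups = pd.Series(indval_groups)
    class_doc = edges[
        (edges["source"] == focus_class) & (edges["target"] == DOC_NODE)
    ]
    if len(class_doc) == 0:
        class_doc = edges[
            (edges["source"] == DOC_NODE) & (edges["target"] == focus_class)
        ]
    if len(class_doc) == 0:
        raise ValueError(f"no significant {focus_class}-DOC edge; consistency undefined")
    rho_class_doc = float(class_doc["rho"].iloc[0])

    rows = []
    for taxon in groups.index:
        hit = edges[
            ((edges["source"] == str(taxon)) & (edges["target"] == focus_class))
            | ((edges["source"] == focus_class) & (edges["target"] == str(taxon)))
        ]
        if len(hit) == 0:
            continue
        rho_tc = float(hit["rho"].iloc[0])
        expected = 1 if groups[taxon] == "high" else -1
        consistent = int(np.sign(rho_tc) * np.sign(rho_class_doc)) == expected
        rows.append(
            {
                "taxon": taxon,
                "indval_group": groups[taxon],
                "rho_with_class": rho_tc,
                "class_rho_with_doc": rho_class_doc,
                "consistent": consistent,
            }
        )
    return pd.DataFrame(rows, columns=["taxon", "indval_group", "rho_with_class", "class_rho_with_doc", "consistent"])


def to_graph(edges: pd.DataFrame) -> nx.Graph:
    """Undirected networkx graph with rho/p/sign edge attributes."""
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["source"], row["target"], rho=row["rho"], p=row["p"], sign=row["sign"])
    return g


def write_sif(edges: pd.DataFrame, path) -> None:
    """Simple-interaction-format export (source, interaction sign, target)."""
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            rel = "pos" if row["sign"] == "+" else "neg"
            fh.write(f"{row['source']}\t{rel}\t{row['target']}\n")


def write_edge_attributes(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)
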