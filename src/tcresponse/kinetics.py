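"""Eight-class kinetic response taxonomy over two sequential contrasts.

A gene is called regulated in a contrast window only when both criteria
agree: |log2 fold change| strictly greater than ``lfc_min`` (default 1,
i.e. twofold) AND p strictly below ``p_max`` (default 0.01). If the two
criteria disagree, no regulation is assumed. The ordered pair of calls
over the windows (0 -> 30 min, 30 min -> 3 h) maps bijectively onto
eight response classes plus "none":

=====  ============  =========================================
label  (call1,call2)  meaning
=====  ============  =========================================
A1     (up, ns)      immediately upregulated to steady state
A2     (down, ns)    immediately downregulated to steady state
B1     (up, up)      immediately and continuously upregulated
B2     (down, down)  immediately and continuously downregulated
C1     (ns, up)      delayed upregulated
C2     (ns, down)    delayed downregulated
D1     (up, down)    transiently upregulated
D2     (down, up)    transiently downregulated
none   (ns, ns)      not regulated
=====  ============  =========================================
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Contrast-window names in kinetic order.
WINDOWS = ("30min-0", "3h-30min")

CLASS_TABLE: dict[tuple[str, str], str] = {
    ("up", "ns"): "A1",
    ("down", "ns"): "A2",
    ("up", "up"): "B1",
    ("down", "down"): "B2",
    ("ns", "up"): "C1",
    ("ns", "down"): "C2",
    ("up", "down"): "D1",
    ("down", "up"): "D2",
    ("ns", "ns"): "none",
}

CLASS_LABELS = ("A1", "A2", "B1", "B2", "C1", "C2", "D1", "D2", "none")


def call_regulation(
    log2fc, p, lfc_min: float = 1.0, p_max: float = 0.01
):
    """Ternary regulation call: up / down / ns.

    Strict inequalities at both gates; NaN in either input yields ``ns``
    with a logged warning. Accepts scalars or arrays.
    """
    lfc = np.asarray(log2fc, dtype=float)
    pv = np.asarray(p, dtype=float)
    scalar = lfc.ndim == 0
    lfc, pv = np.atleast_1d(lfc), np.atleast_1d(pv)
    if np.nanmin(pv, initial=0.0) < 0 or np.nanmax(pv, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    bad = np.isnan(lfc) | np.isnan(pv)
    if bad.any():
        logger.warning("%d NaN statistic(s) treated as ns", int(bad.sum()))
    sig = ~bad & (pv < p_max)
    out = np.where(sig & (lfc > lfc_min), "up",
                   np.where(sig & (lfc < -lfc_min), "down", "ns"))
    return out.item() if scalar else out


def classify(call1: str, call2: str) -> str:
    """Kinetic class for one ordered pair of window calls."""
    try:
        return CLASS_TABLE[(call1, call2)]
    except KeyError:
        raise ValueError(f"invalid call pair ({call1!r}, {call2!r})") from None


def classify_genes(
    contrast_tables: dict[str, pd.DataFrame],
    lfc_min: float = 1.0,
    p_max: float = 0.01,
    windows=WINDOWS,
) -> pd.DataFrame:
    """Per-gene calls and kinetic class from the two contrast tables.

    Returns a table indexed by gene with columns ``call_w1``, ``call_w2``
    and ``kinetic_class``.
    """
    w1, w2 = windows
    t1, t2 = contrast_tables[w1], contrast_tables[w2]
    genes = t1.index
    if not genes.equals(t2.index):
        t2 = t2.reindex(genes)
    c1 = call_regulation(t1["log2fc"].to_numpy(), t1["p"].to_numpy(), lfc_min, p_max)
    c2 = call_regulation(t2["log2fc"].to_numpy(), t2["p"].to_numpy(), lfc_min, p_max)
    labels = [CLASS_TABLE[(a, b)] for a, b in zip(c1, c2)]
    out = pd.DataFrame(
        {"call_w1": c1, "call_w2": c2, "kinetic_class": labels}, index=genes
    )
    out.index.name = "gene_id"
    return out


def summarize_classes(classifications: pd.DataFrame) -> pd.DataFrame:
    """Gene count and member list per kinetic class (all 9 labels)."""
    counts = classifications["kinetic_class"].value_counts()
    rows = []
    for label in CLASS_LABELS:
        members = classifications.index[
            classifications["kinetic_class"] == label
        ].tolist()
        rows.append(
            {"class": label, "n_genes": int(counts.get(label, 0)),
             "genes": ",".join(sorted(members))}
        )
    return pd.DataFrame(rows)


def class_gene_sets(classifications: pd.DataFrame) -> dict[str, set[str]]:
    """Gene set per non-null kinetic class (GMT-ready)."""
    return {
        label: set(classifications.index[classifications["kinetic_class"] == label])
        for label in CLASS_LABELS
        if label != "none"
    }
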