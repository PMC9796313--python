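"""Per-biosynthetic-gene-cluster response summaries.

For each BGC the summary counts how many member genes are up- or
downregulated, decomposed over the two contrast windows. The total is
the size of the UNION of the two window sets — a gene induced in both
windows counts once — with the raw per-window counts reported in
brackets, mirroring the published table layout ``17 (2, 15)``.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)


def summarize_bgc(
    calls: pd.DataFrame, membership: dict[str, list[str]]
) -> pd.DataFrame:
    """Union-semantics up/down summary per cluster.

    Parameters
    ----------
    calls
        Per-gene table with columns ``call_w1`` and ``call_w2`` (from
        :func:`tcresponse.kinetics.classify_genes`). Genes absent from
        the table count as not regulated.
    membership
        Cluster name -> list of member gene ids.

    Returns one row per cluster with columns ``cluster, up_total, up_w1,
    up_w2, down_total, down_w1, down_w2, n_genes_total, up_display,
    down_display``.
    """
    rows = []
    for cluster in membership:
        genes = list(dict.fromkeys(membership[cluster]))
        present = [g for g in genes if g in calls.index]
        if not present:
            logger.warning("cluster %r has no genes in the expression table", cluster)
        sub = calls.loc[present] if present else calls.iloc[0:0]
        up1 = set(sub.index[sub["call_w1"] == "up"])
        up2 = set(sub.index[sub["call_w2"] == "up"])
        dn1 = set(sub.index[sub["call_w1"] == "down"])
        dn2 = set(sub.index[sub["call_w2"] == "down"])
        rows.append({
            "cluster": cluster,
            "up_total": len(up1 | up2),
            "up_w1": len(up1),
            "up_w2": len(up2),
            "down_total": len(dn1 | dn2),
            "down_w1": len(dn1),
            "down_w2": len(dn2),
            "n_genes_total": len(genes),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["up_display"] = [
            _display(r.up_total, r.up_w1, r.up_w2) for r in out.itertuples()
        ]
        out["down_display"] = [
            _display(r.down_total, r.down_w1, r.down_w2) for r in out.itertuples()
        ]
    return out


def _display(total: int, w1: int, w2: int) -> str:
    """Published-table style: ``total (w1, w2)`` or bare ``0``."""
    return "0" if total == 0 else f"{total} ({w1}, {w2})"


def read_membership(path) -> dict[str, list[str]]:
    """Membership TSV with columns ``cluster_id`` and ``gene_id``."""
    tab = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in tab.columns]
    tab.columns = cols
    if not {"cluster_id", "gene_id"} <= set(cols):
        raise ValueError("membership table needs cluster_id and gene_id columns")
    out: dict[str, list[str]] = {}
    for cluster, sub in tab.groupby("cluster_id", sort=False):
        out[str(cluster)] = [str(g) for g in sub["gene_id"]]
    return out


def write_membership(membership: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tgene_id\n")
        for cluster, genes in membership.items():
            for g in genes:
                fh.write(f"{cluster}\t{g}\n")
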