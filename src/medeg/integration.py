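"""Integration of the expression and methylation layers.

For every gene represented on both platforms, the Pearson correlation is
computed over all samples (cases and controls pooled) for every
expression-probe x methylation-probe pair and the pair with the maximum
absolute coefficient is retained.  Genes significant on both layers are
classified as methylation-regulated DEGs (MeDEGs) by the signs of their
expression and methylation changes: opposite signs are the inverse
classes (up-hypo, down-hyper), concordant signs the positive classes.
The correlation is reported as supporting evidence; the class itself is
defined by the direction of the two changes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import PROMOTER_REGIONS
from .exceptions import ValidationError

__all__ = [
    "build_common_gene_universe",
    "pair_probes_by_max_correlation",
    "identify_medegs",
    "IntegrationModel",
    "MeDegResults",
]

logger = logging.getLogger(__name__)

CLASSES = [
    "inverse-up-hypo",
    "inverse-down-hyper",
    "positive-up-hyper",
    "positive-down-hypo",
]


def build_common_gene_universe(
    expr_annotation: pd.DataFrame, meth_contexts: pd.DataFrame
) -> set[str]:
    """Genes with at least one expression probe and one mapped methylation probe."""
    expr_genes = set(expr_annotation["gene_id"].dropna())
    meth_genes = set(meth_contexts["gene_id"].dropna())
    universe = expr_genes & meth_genes
    if not universe:
        warnings.warn("expression and methylation platforms share no genes")
    logger.info("common gene universe: %d genes", len(universe))
    return universe


def _standardize_rows(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (a - mu) / sd
    z[np.ravel(sd == 0), :] = np.nan  # zero variance -> undefined correlation
    return z


def pair_probes_by_max_correlation(
    expr: pd.DataFrame,
    meth: pd.DataFrame,
    universe: set[str],
    expr_mapping: pd.Series,
    meth_mapping: pd.Series,
) -> pd.DataFrame:
    """Per-gene max-|r| pairing of expression and methylation probes.

    Correlations are computed over the pooled samples; ties on |r| are
    broken toward the more negative coefficient, then lexicographic probe
    IDs.  Probe pairs with undefined correlation (zero variance) are
    skipped; genes with no defined pair are excluded and logged.
    """
    if list(expr.columns) != list(meth.columns):
        raise ValidationError("expression and methylation sample sets/order differ")
    n = expr.shape[1]
    expr_by_gene = expr_mapping.dropna().groupby(expr_mapping.dropna()).groups
    meth_by_gene = meth_mapping.dropna().groupby(meth_mapping.dropna()).groups
    ez = pd.DataFrame(
        _standardize_rows(expr.to_numpy(dtype=float)),
        index=expr.index, columns=expr.columns,
    )
    mz = pd.DataFrame(
        _standardize_rows(meth.to_numpy(dtype=float)),
        index=meth.index, columns=meth.columns,
    )
    records, skipped = [], []
    for gene in sorted(universe):
        eps = sorted(p for p in expr_by_gene.get(gene, []) if p in ez.index)
        mps = sorted(p for p in meth_by_gene.get(gene, []) if p in mz.index)
        if not eps or not mps:
            continue
        r = ez.loc[eps].to_numpy() @ mz.loc[mps].to_numpy().T / n
        best = None
        for i, ep in enumerate(eps):
            for j, mp in enumerate(mps):
                rij = r[i, j]
                if not np.isfinite(rij):
                    continue
                key = (-abs(rij), rij, ep, mp)
                if best is None or key < best[0]:
                    best = (key, ep, mp, rij)
        if best is None:
            skipped.append(gene)
            continue
        records.append(
            {
                "gene_id": gene,
                "expr_probe_id": best[1],
                "meth_probe_id": best[2],
                "r": best[3],
                "n_pairs_considered": len(eps) * len(mps),
            }
        )
    if skipped:
        logger.info(
            "%d genes excluded: all candidate pairs had zero variance", len(skipped)
        )
    cols = ["gene_id", "expr_probe_id", "meth_probe_id", "r", "n_pairs_considered"]
    return pd.DataFrame.from_records(records, columns=cols).set_index("gene_id")


def identify_medegs(
    deg_table: pd.DataFrame,
    dmg_table: pd.DataFrame,
    pairs: pd.DataFrame,
    contexts: pd.DataFrame,
    require_paired_dmp: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify genes significant on both layers.

    ``deg_table`` is the gene-level DEG table (with ``is_deg``, ``fc``,
    ``log2_fc``), ``dmg_table`` the DMG table (with ``delta_beta`` and the
    representative ``probe_id``).  Returns the MeDEG record table and the
    overlap counts (total, inverse, positive and the two inverse
    subclasses).  ``promoter_dmp`` flags genes whose representative DMP
    lies in a promoter category (TSS1500, TSS200, 5'UTR, first exon).

    With ``require_paired_dmp`` the gene's max-|r| methylation probe must
    itself be its representative DMP (a stricter reading of the pairing;
    off by default since joint significance plus direction is the
    evidence, not the identity of the best-correlated probe).
    """
    degs = deg_table[deg_table["is_deg"]] if "is_deg" in deg_table else deg_table
    overlap = sorted(set(degs.index) & set(dmg_table.index))
    if require_paired_dmp:
        overlap = [
            g for g in overlap
            if g in pairs.index
            and pairs.loc[g, "meth_probe_id"] == dmg_table.loc[g, "probe_id"]
        ]
    missing = [g for g in overlap if g not in pairs.index]
    if missing:
        raise ValidationError(f"overlap genes missing a pair record: {missing[:10]}")
    rows = []
    for gene in overlap:
        fc = float(degs.loc[gene, "fc"])
        log2_fc = float(degs.loc[gene, "log2_fc"])
        db = float(dmg_table.loc[gene, "delta_beta"])
        up = log2_fc > 0
        hypo = db < 0
        if up and hypo:
            cls = "inverse-up-hypo"
        elif not up and not hypo:
            cls = "inverse-down-hyper"
        elif up:
            cls = "positive-up-hyper"
        else:
            cls = "positive-down-hypo"
        probe = dmg_table.loc[gene, "probe_id"]
        region = contexts["region"].get(probe, "IGR")
        rows.append(
            {
                "gene_id": gene,
                "fc": fc,
                "log2_fc": log2_fc,
                "delta_beta": db,
                "r": float(pairs.loc[gene, "r"]),
                "meth_probe_id": probe,
                "class": cls,
                "promoter_dmp": region in PROMOTER_REGIONS,
            }
        )
    cols = ["gene_id", "fc", "log2_fc", "delta_beta", "r", "meth_probe_id",
            "class", "promoter_dmp"]
    records = pd.DataFrame.from_records(rows, columns=cols).set_index("gene_id")
    cls = records["class"]
    counts = {
        "overlap": len(records),
        "inverse": int(cls.str.startswith("inverse").sum()),
        "positive": int(cls.str.startswith("positive").sum()),
        "inverse_up_hypo": int((cls == "inverse-up-hypo").sum()),
        "inverse_down_hyper": int((cls == "inverse-down-hyper").sum()),
    }
    return records, counts


@dataclass
class MeDegResults:
    """Joined expression/methylation evidence per gene."""

    pairs: pd.DataFrame
    records: pd.DataFrame
    counts: dict[str, int]
    universe: set[str] = field(default_factory=set)

    def summary(self) -> str:
        c = self.counts
        n_prom = int(self.records["promoter_dmp"].sum()) if len(self.records) else 0
        lines = [
            "Methylation-expression integration",
            f"  common gene universe : {len(self.universe)}",
            f"  DEG/DMG overlap      : {c['overlap']}",
            f"  inverse MeDEGs       : {c['inverse']} "
            f"({c['inverse_up_hypo']} up-hypo, {c['inverse_down_hyper']} down-hyper)",
            f"  positive class       : {c['positive']}",
            f"  promoter DMP genes   : {n_prom}",
        ]
        return "\n".join(lines)


class IntegrationModel:
    """Join fitted expression and methylation results into MeDEG calls.

    Parameters
    ----------
    expr_results, meth_results : fitted results from the two layers (must
        carry gene-level tables).
    expr_matrix, meth_matrix : the underlying data matrices used for the
        max-|r| probe pairing (identical sample order required).
    expr_annotation : expression probe -> gene table.
    contexts : methylation probe context table from
        :func:`medeg.annotation.annotate_probes`.
    """

    def __init__(
        self,
        expr_results,
        meth_results,
        expr_matrix: pd.DataFrame,
        meth_matrix: pd.DataFrame,
        expr_annotation: pd.DataFrame,
        contexts: pd.DataFrame,
    ):
        self.expr_results = expr_results
        self.meth_results = meth_results
        self.expr_matrix = expr_matrix
        self.meth_matrix = meth_matrix
        self.expr_annotation = expr_annotation
        self.contexts = contexts

    def fit(self) -> MeDegResults:
        universe = build_common_gene_universe(self.expr_annotation, self.contexts)
        pairs = pair_probes_by_max_correlation(
            self.expr_matrix,
            self.meth_matrix,
            universe,
            self.expr_annotation["gene_id"],
            self.contexts["gene_id"],
        )
        records, counts = identify_medegs(
            self.expr_results.gene_stats,
            self.meth_results.gene_stats,
            pairs,
            self.contexts,
        )
        return MeDegResults(pairs, records, counts, universe)
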