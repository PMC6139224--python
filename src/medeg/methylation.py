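"""Differential methylation on beta-value matrices.

Probe filtering (detection p-value failures, sex chromosomes),
locus-by-locus Wilcoxon rank-sum testing with a median delta-beta effect
filter, BH correction, and collapse of significant positions to
differentially methylated genes.

The default test is the unadjusted rank-sum; a rank test cannot absorb
covariates, so an optional ``mode="ols"`` fits the same covariate model
as the expression layer on logit-transformed beta-values instead.  Both
modes share the median delta-beta effect filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

from .exceptions import ValidationError
from .expression import CASE, CONTROL, _group_indicator, test_differential_expression
from .stats import benjamini_hochberg, rank_sum_matrix

__all__ = [
    "filter_probes",
    "test_differential_methylation",
    "call_dmps",
    "collapse_dmps_to_genes",
    "DifferentialMethylationModel",
    "DifferentialMethylationResults",
]

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}
PROMOTER_REGIONS = {"TSS1500", "TSS200", "5'UTR", "1stExon"}


def filter_probes(
    beta: pd.DataFrame,
    detect: pd.DataFrame,
    annotation: pd.DataFrame,
    p_detect: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove unreliable and sex-chromosome probes.

    A probe is dropped if its detection p-value exceeds ``p_detect`` in at
    least one sample, or if it is annotated to chrX/chrY.  Returns the
    retained matrix and a removal log (probe_id, reason) where the reason
    is the first matching rule (detection before sex chromosome).
    """
    if not beta.index.equals(detect.index) or not beta.columns.equals(detect.columns):
        raise ValidationError("beta and detection matrices must be aligned")
    missing = beta.index.difference(annotation.index)
    if len(missing):
        raise ValidationError(
            f"probes missing from annotation: {sorted(missing)[:10]}"
        )
    bad_detect = (detect > p_detect).any(axis=1)
    on_sex = annotation.loc[beta.index, "chrom"].isin(SEX_CHROMS)
    reasons = np.where(bad_detect, "detection", np.where(on_sex, "sex_chromosome", ""))
    removed = pd.DataFrame(
        {"reason": reasons[reasons != ""]},
        index=beta.index[reasons != ""].rename("probe_id"),
    )
    kept = beta.loc[reasons == ""]
    return kept, removed


def test_differential_methylation(
    beta: pd.DataFrame,
    metadata: pd.DataFrame,
    mode: str = "ranksum",
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-probe case-vs-control test on beta-values.

    ``mode="ranksum"`` (default): two-sided Wilcoxon rank-sum per probe.
    ``mode="ols"``: OLS with covariates on logit(beta), mirroring the
    expression model.  Either way the effect size is
    ``delta_beta = median beta(case) - median beta(control)`` and p-values
    are BH-adjusted across all tested probes.
    """
    arr = beta.to_numpy(dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError("beta-values must lie in [0, 1]")
    samples = list(beta.columns)
    g = _group_indicator(metadata, samples).astype(bool)
    case, ctrl = arr[:, g], arr[:, ~g]
    delta = np.median(case, axis=1) - np.median(ctrl, axis=1)
    if mode == "ranksum":
        w, p_raw = rank_sum_matrix(case, ctrl)
    elif mode == "ols":
        eps = 1e-6
        m = pd.DataFrame(
            logit(np.clip(arr, eps, 1 - eps)), index=beta.index, columns=beta.columns
        )
        ols = test_differential_expression(m, metadata, covariates)
        w, p_raw = ols["t_stat"].to_numpy(), ols["p_raw"].to_numpy()
    else:
        raise ValidationError(f"unknown mode: {mode!r}")
    return pd.DataFrame(
        {
            "delta_beta": delta,
            "w_stat": w,
            "p_raw": p_raw,
            "p_adj": benjamini_hochberg(p_raw),
        },
        index=beta.index.rename("probe_id"),
    )


def call_dmps(
    stats: pd.DataFrame, p_thresh: float = 0.05, db_thresh: float = 0.12
) -> pd.DataFrame:
    """Flag differentially methylated positions.

    A probe is a DMP iff ``p_adj < p_thresh`` and ``|delta_beta| >
    db_thresh`` (both strict); direction is ``hypo`` when the case median
    is lower, ``hyper`` otherwise.
    """
    out = stats.copy()
    out["is_dmp"] = (out["p_adj"] < p_thresh) & (out["delta_beta"].abs() > db_thresh)
    out["direction"] = np.where(out["delta_beta"] < 0, "hypo", "hyper")
    out.loc[~out["is_dmp"], "direction"] = ""
    return out


def collapse_dmps_to_genes(dmps: pd.DataFrame, mapping: pd.Series) -> pd.DataFrame:
    """Collapse significant positions to differentially methylated genes.

    Each gene owning at least one DMP is represented by its probe with the
    largest ``|delta_beta|`` (ties: smaller adjusted p, then lexicographic
    probe ID); that probe decides the gene's hypo/hyper label.  Genes
    carrying DMPs in both directions keep the max-|delta-beta| label and
    are flagged ``both_directions``.
    """
    sig = dmps[dmps["is_dmp"]].copy()
    sig["gene_id"] = mapping.reindex(sig.index)
    sig = sig.dropna(subset=["gene_id"]).reset_index()
    if sig.empty:
        return pd.DataFrame(
            columns=[
                "probe_id", "delta_beta", "w_stat", "p_raw", "p_adj",
                "is_dmp", "direction", "n_dmps", "both_directions",
            ]
        ).rename_axis("gene_id")
    sig["_abs"] = sig["delta_beta"].abs()
    sig = sig.sort_values(["_abs", "p_adj", "probe_id"], ascending=[False, True, True])
    grouped = sig.groupby("gene_id", sort=True)
    out = grouped.first().drop(columns="_abs")
    out["n_dmps"] = grouped.size()
    out["both_directions"] = grouped["direction"].nunique() > 1
    return out


@dataclass
class DifferentialMethylationResults:
    """Fitted differential-methylation results.

    ``probe_stats`` covers retained probes; ``gene_stats`` (DMG table) is
    present when a probe-to-gene mapping was supplied at fit time.
    """

    probe_stats: pd.DataFrame
    gene_stats: pd.DataFrame | None
    removal_log: pd.DataFrame
    p_thresh: float
    db_thresh: float
    mode: str

    @property
    def dmps(self) -> set[str]:
        return set(self.probe_stats.index[self.probe_stats["is_dmp"]])

    @property
    def dmgs(self) -> set[str]:
        if self.gene_stats is None:
            raise ValidationError(
                "gene-level results unavailable: fit with a probe->gene mapping"
            )
        return set(self.gene_stats.index)

    def removal_counts(self) -> dict[str, int]:
        return self.removal_log["reason"].value_counts().to_dict()

    def summary(self) -> str:
        sig = self.probe_stats[self.probe_stats["is_dmp"]]
        hypo = int((sig["direction"] == "hypo").sum())
        hyper = int((sig["direction"] == "hyper").sum())
        lines = [
            f"Differential methylation ({self.mode} test)",
            f"  probes removed: {self.removal_counts() or 0}",
            f"  probes tested : {len(self.probe_stats)}",
            f"  thresholds    : p_adj < {self.p_thresh}, "
            f"|delta beta| > {self.db_thresh}",
            f"  DMPs          : {len(sig)} ({hypo} hypo, {hyper} hyper)",
        ]
        if self.gene_stats is not None:
            lines.append(f"  DMGs          : {len(self.gene_stats)}")
        return "\n".join(lines)


class DifferentialMethylationModel:
    """Case-control differential methylation on a beta-value matrix.

    Parameters
    ----------
    beta, detection : aligned probes x samples matrices of beta-values and
        detection p-values.
    annotation : probe table with a ``chrom`` column (for the sex
        chromosome filter).
    metadata : per-sample table with a ``group`` column.
    probe_gene : optional probe -> gene mapping (e.g. nearest-TSS) that
        enables the DMG collapse.
    """

    def __init__(
        self,
        beta: pd.DataFrame,
        detection: pd.DataFrame,
        annotation: pd.DataFrame,
        metadata: pd.DataFrame,
        probe_gene: pd.Series | None = None,
    ):
        self.beta = beta
        self.detection = detection
        self.annotation = annotation
        self.metadata = metadata
        self.probe_gene = probe_gene

    def fit(
        self,
        p_detect: float = 0.01,
        p_thresh: float = 0.05,
        db_thresh: float = 0.12,
        mode: str = "ranksum",
        covariates: pd.DataFrame | None = None,
    ) -> DifferentialMethylationResults:
        kept, removed = filter_probes(
            self.beta, self.detection, self.annotation, p_detect
        )
        stats = call_dmps(
            test_differential_methylation(kept, self.metadata, mode, covariates),
            p_thresh,
            db_thresh,
        )
        genes = None
        if self.probe_gene is not None:
            genes = collapse_dmps_to_genes(stats, self.probe_gene)
        return DifferentialMethylationResults(
            stats, genes, removed, p_thresh, db_thresh, mode
        )
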