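"""Differential expression between case and control groups.

Per-probe ordinary least-squares model of log2 intensity on group plus
optional covariates (age, sex and the first two expression principal
components), Benjamini-Hochberg correction, threshold calling and
transcript-to-gene collapse by maximal absolute fold change.

The model is deliberately an unmoderated OLS t-test: at cohort sizes in
the high thirties the empirical-Bayes variance moderation used by
microarray-specific packages changes little, and a plain linear model
keeps the fold change and the p-value consistent within one fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import EstimationError, ValidationError
from .stats import benjamini_hochberg

__all__ = [
    "compute_covariate_pcs",
    "test_differential_expression",
    "collapse_probes_to_genes",
    "call_degs",
    "DifferentialExpressionModel",
    "DifferentialExpressionResults",
]

logger = logging.getLogger(__name__)

CASE, CONTROL = "case", "control"


def _group_indicator(metadata: pd.DataFrame, sample_ids) -> np.ndarray:
    if "group" not in metadata.columns:
        raise ValidationError("metadata must have a 'group' column")
    missing = [s for s in sample_ids if s not in metadata.index]
    if missing:
        raise ValidationError(f"samples absent from metadata: {missing[:5]}")
    grp = metadata.loc[sample_ids, "group"]
    bad = sorted(set(grp) - {CASE, CONTROL})
    if bad:
        raise ValidationError(f"unknown group labels: {bad}")
    g = (grp == CASE).to_numpy(dtype=float)
    if g.sum() < 3 or (1 - g).sum() < 3:
        raise ValidationError("each group needs at least 3 samples")
    return g


def compute_covariate_pcs(matrix: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Sample scores on the top-k principal axes of the probe-centered matrix.

    Each probe (row) is centered across samples; sample scores are taken
    from the SVD of the centered matrix.  The sign of each component is
    fixed so that its largest-magnitude probe loading is positive, which
    makes the scores deterministic.

    Returns a DataFrame (samples x k) with columns ``pc1 .. pck``; scores
    have zero mean across samples.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("need at least 2 probes")
    n = matrix.shape[1]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than n_samples={n}")
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = np.zeros((n, k))
    for j in range(min(k, s.size)):
        load = u[:, j]
        sign = np.sign(load[np.argmax(np.abs(load))]) or 1.0
        scores[:, j] = sign * s[j] * vt[j]
    return pd.DataFrame(
        scores, index=matrix.columns, columns=[f"pc{i + 1}" for i in range(k)]
    )


def _build_design(
    group: np.ndarray, covariates: pd.DataFrame | None, sample_ids
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(group), group]
    names = ["intercept", "group"]
    if covariates is not None:
        missing = [s for s in sample_ids if s not in covariates.index]
        if missing:
            raise ValidationError(f"samples absent from covariates: {missing[:5]}")
        cov = covariates.loc[sample_ids]
        for name in cov.columns:
            v = cov[name]
            if v.dtype == object:  # e.g. sex coded M/F
                v = (v == "M").astype(float)
            cols.append(np.asarray(v, dtype=float))
            names.append(str(name))
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the first column whose removal restores full column rank
        for j in range(x.shape[1] - 1, 0, -1):
            sub = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise EstimationError(
                    f"design matrix is singular: column '{names[j]}' is "
                    "collinear with the others"
                )
        raise EstimationError("design matrix is singular")
    return x, names


def test_differential_expression(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-probe OLS test of the case-vs-control group coefficient.

    Fits ``log2 value ~ group (+ covariates)`` by least squares for every
    probe, reporting the group coefficient as the log2 fold change
    (case minus control), its t statistic, the two-sided p-value and the
    BH-adjusted p-value across all probes.  Probes with zero variance are
    reported with log2_fc 0 and p 1 rather than failing the run.
    """
    if matrix.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    samples = list(matrix.columns)
    group = _group_indicator(metadata, samples)
    x, _ = _build_design(group, covariates, samples)

    y = matrix.to_numpy(dtype=float).T  # samples x probes
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # p x probes
    resid = y - x @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    var_g = sigma2 * xtx_inv[1, 1]
    coef = beta[1]

    constant = matrix.nunique(axis=1).to_numpy() == 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / np.sqrt(var_g)
    t = np.where(np.isfinite(t), t, 0.0)
    p_raw = 2 * sps.t.sf(np.abs(t), df)
    coef = np.where(constant, 0.0, coef)
    t = np.where(constant, 0.0, t)
    p_raw = np.where(constant, 1.0, p_raw)

    fc = np.sign(coef) * 2.0 ** np.abs(coef)
    fc = np.where(coef == 0, 1.0, fc)
    return pd.DataFrame(
        {
            "log2_fc": coef,
            "fc": fc,
            "t_stat": t,
            "p_raw": p_raw,
            "p_adj": benjamini_hochberg(p_raw),
        },
        index=matrix.index.rename("probe_id"),
    )


def collapse_probes_to_genes(
    stats: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Collapse probe-level statistics to one representative probe per gene.

    The probe with the largest ``|fc|`` represents the gene; ties are
    broken by smaller adjusted p, then lexicographic probe ID.  Probes
    without a gene mapping are dropped (count logged).
    """
    if "gene_id" not in annotation.columns:
        raise ValidationError("annotation must have a 'gene_id' column")
    tab = stats.join(annotation["gene_id"], how="left")
    unmapped = tab["gene_id"].isna().sum()
    if unmapped:
        logger.info("dropping %d probes without a gene mapping", unmapped)
        tab = tab.dropna(subset=["gene_id"])
    tab = tab.reset_index()
    tab["_absfc"] = tab["fc"].abs()
    tab = tab.sort_values(
        ["_absfc", "p_adj", "probe_id"], ascending=[False, True, True]
    )
    out = tab.groupby("gene_id", sort=True).first().drop(columns="_absfc")
    return out


def call_degs(
    gene_stats: pd.DataFrame,
    p_thresh: float = 0.05,
    fc_thresh: float = 1.5,
) -> pd.DataFrame:
    """Flag differentially expressed genes.

    A gene is a DEG iff ``p_adj < p_thresh`` and ``|fc| > fc_thresh``
    (both strict); direction is the sign of the log2 fold change.
    """
    out = gene_stats.copy()
    out["is_deg"] = (out["p_adj"] < p_thresh) & (out["fc"].abs() > fc_thresh)
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    out.loc[~out["is_deg"], "direction"] = ""
    return out


@dataclass
class DifferentialExpressionResults:
    """Fitted differential-expression results.

    Attributes
    ----------
    probe_stats : per-probe statistics (log2_fc, fc, t_stat, p_raw, p_adj)
    gene_stats : gene-level table after max-|FC| collapse and DEG calling
        (``None`` when no probe annotation was supplied)
    """

    probe_stats: pd.DataFrame
    gene_stats: pd.DataFrame | None
    p_thresh: float
    fc_thresh: float
    covariate_names: list[str] = field(default_factory=list)

    @property
    def degs(self) -> set[str]:
        self._require_genes()
        return set(self.gene_stats.index[self.gene_stats["is_deg"]])

    @property
    def up(self) -> list[str]:
        self._require_genes()
        g = self.gene_stats
        return sorted(g.index[g["is_deg"] & (g["direction"] == "up")])

    @property
    def down(self) -> list[str]:
        self._require_genes()
        g = self.gene_stats
        return sorted(g.index[g["is_deg"] & (g["direction"] == "down")])

    def _require_genes(self):
        if self.gene_stats is None:
            raise ValidationError(
                "gene-level results unavailable: fit with a probe annotation"
            )

    def summary(self) -> str:
        lines = [
            "Differential expression (OLS group test)",
            f"  probes tested : {len(self.probe_stats)}",
            f"  covariates    : {', '.join(self.covariate_names) or 'none'}",
            f"  thresholds    : p_adj < {self.p_thresh}, |FC| > {self.fc_thresh}",
        ]
        if self.gene_stats is not None:
            lines += [
                f"  genes         : {len(self.gene_stats)}",
                f"  DEGs          : {len(self.degs)} "
                f"({len(self.up)} up, {len(self.down)} down)",
            ]
        return "\n".join(lines)


class DifferentialExpressionModel:
    """Case-control differential expression on a log2 intensity matrix.

    Parameters
    ----------
    matrix : probes x samples log2 expression values.
    metadata : per-sample table with a ``group`` column (``case`` /
        ``control``) and, for the default covariate set, ``age`` and
        ``sex`` columns.
    covariates : ``"auto"`` (default) builds age, sex and the first two
        expression principal components from the data; a DataFrame is
        used as-is; ``None`` fits the group-only model.
    annotation : optional probe -> gene table enabling the gene-level
        collapse and DEG calling.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        metadata: pd.DataFrame,
        covariates: str | pd.DataFrame | None = "auto",
        annotation: pd.DataFrame | None = None,
    ):
        self.matrix = matrix
        self.metadata = metadata
        self.annotation = annotation
        if isinstance(covariates, str):
            if covariates != "auto":
                raise ValidationError("covariates must be 'auto', None or a DataFrame")
            pcs = compute_covariate_pcs(matrix, k=2)
            cov = metadata.loc[matrix.columns, ["age", "sex"]].copy()
            self.covariates = cov.join(pcs)
        else:
            self.covariates = covariates

    def fit(
        self, p_thresh: float = 0.05, fc_thresh: float = 1.5
    ) -> DifferentialExpressionResults:
        probe_stats = test_differential_expression(
            self.matrix, self.metadata, self.covariates
        )
        gene_stats = None
        if self.annotation is not None:
            gene_stats = call_degs(
                collapse_probes_to_genes(probe_stats, self.annotation),
                p_thresh,
                fc_thresh,
            )
        names = [] if self.covariates is None else list(self.covariates.columns)
        return DifferentialExpressionResults(
            probe_stats, gene_stats, p_thresh, fc_thresh, names
        )
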