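"""Downstream analyses: gene-set enrichment, clinical subgroup contrasts
and qPCR relative quantities.

The enrichment test is a generic one-sided hypergeometric over-representation
test against a user-supplied background with BH correction across sets; it
stands in for external annotation services and makes no attempt to match
any proprietary pathway database's scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError
from .stats import benjamini_hochberg, rank_sum_matrix

__all__ = [
    "read_gmt",
    "hypergeometric_enrichment",
    "compare_subgroups",
    "relative_quantity",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (set name, description, genes...)."""
    from gseapy import read_gmt as _read_gmt

    return {name: list(genes) for name, genes in _read_gmt(str(path)).items()}


def hypergeometric_enrichment(
    query: set[str],
    collections: dict[str, list[str] | set[str]],
    background: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Each set is intersected with the background before testing; the
    p-value is the upper tail P[X >= overlap].  BH correction is applied
    across sets.  The query must be a subset of the background.
    """
    background = set(background)
    if not background:
        raise ValidationError("background gene set is empty")
    query = set(query)
    if not query <= background:
        raise ValidationError("query genes must be a subset of the background")
    m = len(background)
    nq = len(query)
    rows = []
    for name in collections:
        s = set(collections[name]) & background
        k = len(query & s)
        # P[X >= k] for X ~ Hypergeom(M=m, K=|s|, n=nq)
        p = float(sps.hypergeom.sf(k - 1, m, len(s), nq))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(s),
                "query_size": nq,
                "background_size": m,
                "p_raw": min(p, 1.0),
            }
        )
    out = pd.DataFrame.from_records(
        rows,
        columns=["set_name", "overlap", "set_size", "query_size",
                 "background_size", "p_raw"],
    )
    out["p_adj"] = benjamini_hochberg(out["p_raw"]) if len(out) else []
    return out.sort_values("p_raw", kind="stable").reset_index(drop=True)


def compare_subgroups(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    grouping: str = "ild",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Contrast per-gene measurements between case subgroups.

    For ``grouping="ild"`` compares cases with interstitial lung disease
    (``ild == 1``) against cases without, per gene, by the two-sided
    rank-sum test.  Significance is at raw p < ``alpha`` (no multiplicity
    correction: these are small confirmatory contrasts on a handful of
    genes).  Direction is the sign of the subgroup median difference.
    """
    if grouping != "ild":
        raise ValidationError(f"unknown grouping: {grouping!r}")
    cases = metadata[metadata["group"] == "case"]
    in_sub = cases.index[cases["ild"] == 1]
    out_sub = cases.index[cases["ild"] == 0]
    in_sub = [s for s in in_sub if s in values.columns]
    out_sub = [s for s in out_sub if s in values.columns]
    if len(in_sub) < 2 or len(out_sub) < 2:
        raise ValidationError("each subgroup needs at least 2 samples")
    a = values[in_sub].to_numpy(dtype=float)
    b = values[out_sub].to_numpy(dtype=float)
    w, p = rank_sum_matrix(a, b)
    diff = np.median(a, axis=1) - np.median(b, axis=1)
    return pd.DataFrame(
        {
            "w_stat": w,
            "p_raw": p,
            "median_diff": diff,
            "direction": np.where(diff < 0, "down", "up"),
            "significant": p < alpha,
        },
        index=values.index.rename("gene_id"),
    )


def relative_quantity(
    ct_target: float,
    ct_reference: float,
    calibrator_ct_target: float,
    calibrator_ct_reference: float,
) -> float:
    """qPCR relative quantity by the 2^-ddCt method.

    The target gene's cycle threshold is normalized to a housekeeping
    reference within each sample, then to a calibrator sample:
    ``rq = 2 ** -[(ct_target - ct_reference) -
    (calibrator_ct_target - calibrator_ct_reference)]``.
    """
    cts = [ct_target, ct_reference, calibrator_ct_target, calibrator_ct_reference]
    if not np.all(np.isfinite(cts)):
        raise ValidationError("all Ct values must be finite")
    ddct = (ct_target - ct_reference) - (
        calibrator_ct_target - calibrator_ct_reference
    )
    return float(2.0 ** -ddct)
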