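"""Genomic annotation of methylation probes.

Nearest-TSS gene mapping (strictly within 10 kb), strand-aware gene-region
classification (TSS200, TSS1500, 5'UTR, first exon, body, 3'UTR, IGR) and
CpG-island context (island / shore / shelf / open sea, with the platform's
standard 2 kb / 4 kb distance bands).

All coordinates are 0-based; intervals are half-open (BED convention).
Gene models carry ``tss`` explicitly: for a plus-strand gene it equals
``tx_start``, for a minus-strand gene ``tx_end - 1``.  ``first_exon_end``
is the genomic boundary of the first exon away from the TSS, i.e. the
exclusive upper bound on the plus strand and the inclusive lower bound on
the minus strand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "map_probe_to_gene",
    "classify_region",
    "classify_cpg_context",
    "annotate_probes",
    "summarize_genomic_distribution",
    "percent",
    "REGIONS",
    "CPG_CONTEXTS",
    "PROMOTER_REGIONS",
]

REGIONS = ["TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "IGR"]
CPG_CONTEXTS = ["island", "shore", "shelf", "open_sea"]
PROMOTER_REGIONS = {"TSS1500", "TSS200", "5'UTR", "1stExon"}

SHORE_BP = 2000
SHELF_BP = 4000


def map_probe_to_gene(
    pos: int, chrom: str, genes: pd.DataFrame, max_dist: int = 10_000
) -> str | None:
    """Nearest-TSS gene for a probe position, or ``None``.

    The gene whose TSS is nearest in absolute distance is returned when
    that distance is strictly below ``max_dist``; exact-distance ties go
    to the lexicographically smallest gene ID.
    """
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return None
    dist = (sub["tss"] - pos).abs()
    dmin = dist.min()
    if dmin >= max_dist:
        return None
    return min(sub.index[dist == dmin])


def _check_gene_model(gene: pd.Series) -> None:
    if not (
        gene["tx_start"] <= gene["cds_start"] <= gene["cds_end"] <= gene["tx_end"]
    ):
        raise ValidationError(
            f"malformed gene model: CDS outside transcript for {gene.name!r}"
        )


def classify_region(pos: int, gene: pd.Series) -> str:
    """Gene-region category of a probe mapped to ``gene``.

    Precedence among overlapping categories follows the 450K annotation
    convention: TSS200 > TSS1500 > 5'UTR > 1stExon > 3'UTR > Body.
    Positions outside every defined feature are IGR even when a nearest
    gene exists.
    """
    _check_gene_model(gene)
    tss = int(gene["tss"])
    tx_start, tx_end = int(gene["tx_start"]), int(gene["tx_end"])
    cds_start, cds_end = int(gene["cds_start"]), int(gene["cds_end"])
    fee = int(gene["first_exon_end"])
    if gene["strand"] == "+":
        upstream = tss - pos
        utr5 = tx_start <= pos < cds_start
        exon1 = tss <= pos < fee
        utr3 = cds_end <= pos < tx_end
    else:
        upstream = pos - tss
        utr5 = cds_end <= pos < tx_end
        exon1 = fee <= pos < tx_end
        utr3 = tx_start <= pos < cds_start
    in_tx = tx_start <= pos < tx_end
    if 1 <= upstream <= 200:
        return "TSS200"
    if 201 <= upstream <= 1500:
        return "TSS1500"
    if in_tx and utr5:
        return "5'UTR"
    if in_tx and exon1:
        return "1stExon"
    if in_tx and utr3:
        return "3'UTR"
    if in_tx:
        return "Body"
    return "IGR"


def classify_cpg_context(pos: int, chrom: str, islands: pd.DataFrame) -> str:
    """CpG context of a position given island intervals (BED, half-open).

    Inside an island -> ``island``; within 2 kb of an island boundary ->
    ``shore``; within 4 kb -> ``shelf``; otherwise ``open_sea``.
    """
    sub = islands[islands["chrom"] == chrom]
    if sub.empty:
        return "open_sea"
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    inside = (start <= pos) & (pos < end)
    if inside.any():
        return "island"
    gap = np.where(pos < start, start - pos, pos - end + 1)
    d = gap.min()
    if d <= SHORE_BP:
        return "shore"
    if d <= SHELF_BP:
        return "shelf"
    return "open_sea"


def _nearest_gene_vec(
    pos: np.ndarray, genes: pd.DataFrame, max_dist: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nearest-TSS lookup within one chromosome.

    Returns (gene_id object array with None for unmapped, unsigned
    distance array with NaN for unmapped).  Exact-distance ties resolve
    to the lexicographically smallest gene ID, matching
    :func:`map_probe_to_gene`.
    """
    order = np.lexsort((genes.index.to_numpy(), genes["tss"].to_numpy()))
    tss = genes["tss"].to_numpy()[order]
    # min gene id per distinct tss value (covers same-TSS ties)
    min_gene = (
        pd.Series(genes.index.to_numpy()[order], index=tss).groupby(level=0).min()
    )
    utss = min_gene.index.to_numpy()
    ugene = min_gene.to_numpy()
    i = np.searchsorted(utss, pos)
    left = np.clip(i - 1, 0, len(utss) - 1)
    right = np.clip(i, 0, len(utss) - 1)
    d_left = np.abs(pos - utss[left])
    d_right = np.abs(pos - utss[right])
    dmin = np.minimum(d_left, d_right)
    pick_left = d_left <= d_right  # provisional; equal-distance tie fixed below
    choice = np.where(pick_left, ugene[left], ugene[right])
    tie = (d_left == d_right) & (left != right)
    if tie.any():
        choice[tie] = np.minimum(ugene[left[tie]], ugene[right[tie]])
    mapped = dmin < max_dist
    gene = np.where(mapped, choice, None)
    dist = np.where(mapped, dmin.astype(float), np.nan)
    return gene, dist


def _regions_vec(pos: np.ndarray, genes: pd.DataFrame) -> np.ndarray:
    """Vectorized strand-aware region classification (same rules as
    :func:`classify_region`); ``genes`` holds one row per probe."""
    bad = ~(
        (genes["tx_start"] <= genes["cds_start"])
        & (genes["cds_start"] <= genes["cds_end"])
        & (genes["cds_end"] <= genes["tx_end"])
    )
    if bad.any():
        raise ValidationError(
            f"malformed gene model: CDS outside transcript for "
            f"{sorted(set(genes.index[bad]))[:5]!r}"
        )
    tss = genes["tss"].to_numpy()
    tx_start = genes["tx_start"].to_numpy()
    tx_end = genes["tx_end"].to_numpy()
    cds_start = genes["cds_start"].to_numpy()
    cds_end = genes["cds_end"].to_numpy()
    fee = genes["first_exon_end"].to_numpy()
    plus = (genes["strand"] == "+").to_numpy()
    upstream = np.where(plus, tss - pos, pos - tss)
    utr5 = np.where(plus, (tx_start <= pos) & (pos < cds_start),
                    (cds_end <= pos) & (pos < tx_end))
    exon1 = np.where(plus, (tss <= pos) & (pos < fee), (fee <= pos) & (pos < tx_end))
    utr3 = np.where(plus, (cds_end <= pos) & (pos < tx_end),
                    (tx_start <= pos) & (pos < cds_start))
    in_tx = (tx_start <= pos) & (pos < tx_end)
    out = np.full(len(pos), "IGR", dtype=object)
    out[in_tx] = "Body"
    out[in_tx & utr3] = "3'UTR"
    out[in_tx & exon1] = "1stExon"
    out[in_tx & utr5] = "5'UTR"
    out[(201 <= upstream) & (upstream <= 1500)] = "TSS1500"
    out[(1 <= upstream) & (upstream <= 200)] = "TSS200"
    return out


def _cpg_context_vec(pos: np.ndarray, islands: pd.DataFrame) -> np.ndarray:
    """Vectorized CpG context for one chromosome's sorted, disjoint islands."""
    out = np.full(len(pos), "open_sea", dtype=object)
    if islands.empty:
        return out
    starts = islands["start"].to_numpy()
    ends = islands["end"].to_numpy()
    i = np.searchsorted(starts, pos, side="right") - 1
    prev = np.clip(i, 0, len(starts) - 1)
    inside = (i >= 0) & (pos < ends[prev])
    nxt = np.clip(i + 1, 0, len(starts) - 1)
    d_prev = np.where(i >= 0, pos - ends[prev] + 1, np.iinfo(np.int64).max)
    d_next = np.where(i + 1 < len(starts), starts[nxt] - pos,
                      np.iinfo(np.int64).max)
    d = np.minimum(d_prev, d_next)
    out[d <= SHELF_BP] = "shelf"
    out[d <= SHORE_BP] = "shore"
    out[inside] = "island"
    return out


def annotate_probes(
    probe_annotation: pd.DataFrame,
    gene_models: pd.DataFrame,
    islands: pd.DataFrame,
    max_dist: int = 10_000,
) -> pd.DataFrame:
    """Build the full probe context table.

    Returns a DataFrame indexed by probe ID with ``gene_id`` (nearest TSS
    within ``max_dist``, or NaN), ``tss_distance`` (unsigned bp), the
    gene-region category and the CpG-island context.  Vectorized per
    chromosome; equivalent to applying :func:`map_probe_to_gene`,
    :func:`classify_region` and :func:`classify_cpg_context` probe by
    probe.
    """
    out = pd.DataFrame(
        {
            "gene_id": pd.Series(None, index=probe_annotation.index, dtype=object),
            "tss_distance": np.nan,
            "region": "IGR",
            "cpg_context": "open_sea",
        }
    )
    out.index.name = "probe_id"
    islands = islands.sort_values(["chrom", "start"])
    for chrom, probes in probe_annotation.groupby("chrom"):
        pos = probes["pos"].to_numpy(dtype=int)
        isl = islands[islands["chrom"] == chrom]
        out.loc[probes.index, "cpg_context"] = _cpg_context_vec(pos, isl)
        sub = gene_models[gene_models["chrom"] == chrom]
        if sub.empty:
            continue
        gene, dist = _nearest_gene_vec(pos, sub, max_dist)
        out.loc[probes.index, "gene_id"] = gene
        out.loc[probes.index, "tss_distance"] = dist
        mapped = np.array([g is not None for g in gene])
        if mapped.any():
            rows = sub.loc[gene[mapped].astype(str)]
            regions = _regions_vec(pos[mapped], rows)
            idx = probes.index[mapped]
            out.loc[idx, "region"] = regions
    return out


def percent(count: int, total: int) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    if total == 0:
        raise ValidationError("total must be positive")
    return int(np.floor(100.0 * count / total + 0.5))


def summarize_genomic_distribution(
    contexts: pd.DataFrame, dmps: set[str] | list[str]
) -> pd.DataFrame:
    """Counts and integer percentages of DMPs per CpG context and region.

    Returns a tidy table with columns ``kind`` (cpg_context / region),
    ``category``, ``count`` and ``percent``; counts within each kind sum
    to the number of DMPs.  An empty DMP set yields an empty table.
    """
    dmps = [p for p in dmps if p in contexts.index]
    if not dmps:
        return pd.DataFrame(columns=["kind", "category", "count", "percent"])
    sub = contexts.loc[dmps]
    total = len(sub)
    rows = []
    for kind, order in (("cpg_context", CPG_CONTEXTS), ("region", REGIONS)):
        counts = sub[kind].value_counts()
        for cat in order:
            c = int(counts.get(cat, 0))
            rows.append(
                {"kind": kind, "category": cat, "count": c,
                 "percent": percent(c, total)}
            )
    return pd.DataFrame(rows)
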