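"""Synthetic paired expression/methylation cohort generator.

Emulates a two-group microarray study (18 cases vs 19 controls by
default): log2 expression intensities with planted fold changes,
beta-value methylation with planted median differences, a subset of
genes whose expression and methylation are coupled through a shared
per-sample latent factor (inversely for the canonical
methylation-regulated classes, concordantly for the positive classes),
detection p-value failures, sex-chromosome probes, and full annotation
files (probe-to-gene maps, gene models with TSS/exon/UTR structure on a
synthetic linear chromosome, CpG islands) so that every downstream stage
of the pipeline runs without external data.

Beta-values are produced through a logit-normal latent: group shifts and
coupling compose additively on the logit scale, and because the noise is
symmetric the population median beta-difference of a planted probe
equals the configured effect exactly (the latent shift is calibrated per
probe from its baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import ConfigurationError

__all__ = ["SimConfig", "SyntheticTruth", "Cohort", "generate_cohort",
           "simulate_feature_matrix", "write_cohort", "read_cohort"]

GENE_SLOT = 20_000  # bp reserved per gene on the synthetic chromosome
CHROM = "chr1"

MEDEG_CLASSES = [
    "inverse-up-hypo",
    "inverse-down-hyper",
    "positive-up-hyper",
    "positive-down-hypo",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 18 cases vs 19 controls,
    fold-change and delta-beta effects sitting above the calling
    thresholds (|FC| > 1.5, |delta beta| > 0.12), and 20 inverse plus 5
    positive methylation-coupled genes.
    """

    n_case: int = 18
    n_control: int = 19
    n_genes: int = 2000
    n_expr_probes_per_gene: int = 2
    n_meth_probes: int = 5000
    n_deg: int = 100
    n_dmp: int = 150
    n_medeg_inverse: int = 20
    n_medeg_positive: int = 5
    log2_fc_effect: float = 1.0
    delta_beta_effect: float = 0.20
    coupling_strength: float = 0.8
    coupling_factor_sd: float = 0.3
    expr_noise_sd: float = 0.3
    meth_noise_sd: float = 0.3
    n_nuisance_factors: int = 2
    nuisance_loading_sd: float = 0.4
    frac_failed_detection: float = 0.01
    frac_sex_chrom: float = 0.02
    n_ild: int = 10
    age_effect: float = 0.0
    sex_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        counts = [
            self.n_case, self.n_control, self.n_genes, self.n_meth_probes,
            self.n_deg, self.n_dmp, self.n_medeg_inverse, self.n_medeg_positive,
            self.n_ild,
        ]
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be non-negative")
        if not 1 <= self.n_expr_probes_per_gene <= 3:
            raise ConfigurationError("n_expr_probes_per_gene must be in 1..3")
        n_medeg = self.n_medeg_inverse + self.n_medeg_positive
        if n_medeg > min(self.n_deg, self.n_dmp):
            raise ConfigurationError(
                "n_medeg_inverse + n_medeg_positive must not exceed "
                "min(n_deg, n_dmp)"
            )
        if self.n_deg > self.n_genes:
            raise ConfigurationError("n_deg exceeds the gene pool")
        if self.n_dmp > self.n_meth_probes:
            raise ConfigurationError("n_dmp exceeds the methylation probe pool")
        if not 0 < self.delta_beta_effect < 1:
            raise ConfigurationError("delta_beta_effect must be in (0, 1)")
        if not 0 <= self.frac_failed_detection < 1:
            raise ConfigurationError("frac_failed_detection must be in [0, 1)")
        if not 0 <= self.frac_sex_chrom < 1:
            raise ConfigurationError("frac_sex_chrom must be in [0, 1)")
        if self.n_ild > self.n_case:
            raise ConfigurationError("n_ild exceeds the number of cases")


@dataclass
class SyntheticTruth:
    """Planted identities and effect sizes, for recovery testing."""

    deg_effects: dict[str, float] = field(default_factory=dict)
    dmp_effects: dict[str, float] = field(default_factory=dict)
    medeg_class: dict[str, str] = field(default_factory=dict)
    medeg_meth_probe: dict[str, str] = field(default_factory=dict)

    @property
    def deg_genes(self) -> set[str]:
        return set(self.deg_effects)

    @property
    def dmp_probes(self) -> set[str]:
        return set(self.dmp_effects)

    @property
    def medeg_genes(self) -> set[str]:
        return set(self.medeg_class)

    def validate(self) -> None:
        for gene, cls in self.medeg_class.items():
            if cls not in MEDEG_CLASSES:
                raise ConfigurationError(f"unknown MeDEG class {cls!r}")
            if gene not in self.deg_effects:
                raise ConfigurationError(f"MeDEG {gene} is not a planted DEG")
            probe = self.medeg_meth_probe.get(gene)
            if probe not in self.dmp_effects:
                raise ConfigurationError(f"MeDEG {gene} owns no planted DMP")
            up = self.deg_effects[gene] > 0
            hypo = self.dmp_effects[probe] < 0
            expected = {
                (True, True): "inverse-up-hypo",
                (False, False): "inverse-down-hyper",
                (True, False): "positive-up-hyper",
                (False, True): "positive-down-hypo",
            }[(up, hypo)]
            if cls != expected:
                raise ConfigurationError(
                    f"MeDEG {gene}: class {cls} inconsistent with planted signs"
                )


@dataclass
class Cohort:
    """A generated cohort: matrices, annotations, metadata and truth."""

    expression: pd.DataFrame
    methylation: pd.DataFrame
    detection: pd.DataFrame
    metadata: pd.DataFrame
    expr_annotation: pd.DataFrame
    meth_annotation: pd.DataFrame
    gene_models: pd.DataFrame
    cpg_islands: pd.DataFrame
    truth: SyntheticTruth
    config: SimConfig | None = None


def _gene_models(cfg: SimConfig, rng) -> pd.DataFrame:
    ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    base = np.arange(cfg.n_genes) * GENE_SLOT
    strand = rng.choice(["+", "-"], size=cfg.n_genes)
    tx_start = base + 5000
    tx_end = base + 15_000
    tss = np.where(strand == "+", tx_start, tx_end - 1)
    first_exon_end = np.where(strand == "+", tx_start + 600, tx_end - 600)
    return pd.DataFrame(
        {
            "chrom": CHROM,
            "strand": strand,
            "tss": tss,
            "tx_start": tx_start,
            "tx_end": tx_end,
            "cds_start": tx_start + 400,
            "cds_end": tx_end - 400,
            "first_exon_end": first_exon_end,
        },
        index=pd.Index(ids, name="gene_id"),
    )


def _cpg_islands(cfg: SimConfig, genes: pd.DataFrame, desert_base: int, rng
                 ) -> pd.DataFrame:
    rows = []
    has_island = rng.random(len(genes)) < 0.3
    for (gid, g), flag in zip(genes.iterrows(), has_island):
        if flag:
            s = max(0, int(g["tss"]) - 400)
            rows.append((CHROM, s, s + 800))
    for k in range(3):
        s = desert_base + k * 50_000
        rows.append((CHROM, s, s + 800))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _feature_position(gene: pd.Series, kind: str) -> int:
    """A genomic position falling in the requested region of a gene."""
    tss = int(gene["tss"])
    tx_start, tx_end = int(gene["tx_start"]), int(gene["tx_end"])
    plus = gene["strand"] == "+"
    if kind == "tss200":
        return tss - 100 if plus else tss + 100
    if kind == "tss1500":
        return tss - 1000 if plus else tss + 1000
    if kind == "utr5":
        return tx_start + 200 if plus else tx_end - 200
    if kind == "exon1":
        return tx_start + 500 if plus else tx_end - 500
    if kind == "body":
        return tx_start + 5000
    if kind == "utr3":
        return tx_end - 200 if plus else tx_start + 200
    raise ValueError(kind)


def _medeg_classes(cfg: SimConfig) -> list[str]:
    n_inv_up = int(round(0.6 * cfg.n_medeg_inverse))
    n_pos_up = int(round(0.2 * cfg.n_medeg_positive))
    return (
        ["inverse-up-hypo"] * n_inv_up
        + ["inverse-down-hyper"] * (cfg.n_medeg_inverse - n_inv_up)
        + ["positive-up-hyper"] * n_pos_up
        + ["positive-down-hypo"] * (cfg.n_medeg_positive - n_pos_up)
    )


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a full synthetic cohort; the seed fully determines it."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_case + cfg.n_control

    # --- samples -------------------------------------------------------
    samples = [f"SSc{i + 1:02d}" for i in range(cfg.n_case)] + [
        f"NC{i + 1:02d}" for i in range(cfg.n_control)
    ]
    case = np.r_[np.ones(cfg.n_case), np.zeros(cfg.n_control)]
    age = np.round(np.clip(rng.normal(43, 10, n), 18, 80), 1)
    sex = rng.choice(["M", "F"], size=n)
    ild = np.zeros(n, dtype=int)
    ild[: cfg.n_ild] = 1  # only meaningful on cases, which come first
    metadata = pd.DataFrame(
        {
            "group": np.where(case == 1, "case", "control"),
            "age": age,
            "sex": sex,
            "ild": ild,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    # --- genes, islands ------------------------------------------------
    genes = _gene_models(cfg, rng)
    desert_base = cfg.n_genes * GENE_SLOT + 50_000
    islands = _cpg_islands(cfg, genes, desert_base, rng)

    # --- planted identities --------------------------------------------
    perm = rng.permutation(cfg.n_genes)
    gene_ids = genes.index.to_numpy()
    n_medeg = cfg.n_medeg_inverse + cfg.n_medeg_positive
    medeg_genes = list(gene_ids[perm[:n_medeg]])
    deg_genes = list(gene_ids[perm[: cfg.n_deg]])
    classes = _medeg_classes(cfg)

    n_dual = 2 if cfg.n_dmp - n_medeg >= 2 and cfg.n_deg + 1 <= cfg.n_genes else 0
    n_other = cfg.n_dmp - n_medeg - n_dual
    n_intergenic_dmp = min(5, n_other)
    n_other_gene = n_other - n_intergenic_dmp
    extra_needed = (1 if n_dual else 0) + n_other_gene
    if cfg.n_deg + extra_needed > cfg.n_genes:
        raise ConfigurationError(
            "not enough genes to host the requested non-MeDEG DMPs"
        )
    extra_genes = list(gene_ids[perm[cfg.n_deg: cfg.n_deg + extra_needed]])
    dual_gene = extra_genes[0] if n_dual else None
    dmg_only_genes = extra_genes[1:] if n_dual else extra_genes

    # --- expression effects --------------------------------------------
    deg_sign: dict[str, float] = {}
    for gene, cls in zip(medeg_genes, classes):
        deg_sign[gene] = 1.0 if "up" in cls else -1.0
    for gene in deg_genes[n_medeg:]:
        deg_sign[gene] = float(rng.choice([-1.0, 1.0]))

    # --- methylation probe layout --------------------------------------
    probe_ids = [f"cg{i:06d}" for i in range(cfg.n_meth_probes)]
    n_sex = int(round(cfg.frac_sex_chrom * cfg.n_meth_probes))
    n_scatter = cfg.n_meth_probes - cfg.n_dmp - n_sex
    if n_scatter < 0:
        raise ConfigurationError("n_meth_probes too small for planted + sex probes")
    n_failed = int(round(cfg.frac_failed_detection * cfg.n_meth_probes))
    if n_failed > n_scatter:
        raise ConfigurationError("frac_failed_detection exceeds the free probe pool")

    chroms = np.full(cfg.n_meth_probes, CHROM, dtype=object)
    positions = np.zeros(cfg.n_meth_probes, dtype=int)
    dmp_sign = np.zeros(cfg.n_meth_probes)  # nonzero marks a planted DMP

    idx = 0
    medeg_probe: dict[str, str] = {}
    prom_kinds = ["tss200", "tss1500", "utr5", "exon1"]
    n_prom = int(round(0.6 * n_medeg))
    for k, (gene, cls) in enumerate(zip(medeg_genes, classes)):
        kind = prom_kinds[k % len(prom_kinds)] if k < n_prom else "body"
        positions[idx] = _feature_position(genes.loc[gene], kind)
        dmp_sign[idx] = -1.0 if "hypo" in cls else 1.0
        medeg_probe[gene] = probe_ids[idx]
        idx += 1
    if n_dual:
        for kind, s in (("tss200", 1.0), ("body", -1.0)):
            positions[idx] = _feature_position(genes.loc[dual_gene], kind)
            dmp_sign[idx] = s
            idx += 1
    other_kinds = ["tss200", "tss1500", "utr5", "exon1", "body", "utr3"]
    for k, gene in enumerate(dmg_only_genes):
        positions[idx] = _feature_position(genes.loc[gene], other_kinds[k % 6])
        dmp_sign[idx] = float(rng.choice([-1.0, 1.0]))
        idx += 1
    for k in range(n_intergenic_dmp):
        positions[idx] = desert_base + 200_000 + k * 10_000
        dmp_sign[idx] = float(rng.choice([-1.0, 1.0]))
        idx += 1
    sex_slice = slice(idx, idx + n_sex)
    for k in range(n_sex):
        chroms[idx] = "chrX" if k % 2 == 0 else "chrY"
        positions[idx] = 1_000_000 + k * 10_000
        idx += 1
    scatter_slice = slice(idx, cfg.n_meth_probes)
    for k in range(idx, cfg.n_meth_probes):
        if cfg.n_genes == 0 or rng.random() < 0.1:
            positions[k] = desert_base + int(rng.integers(0, 300_000))
        else:
            g = genes.iloc[int(rng.integers(cfg.n_genes))]
            off = int(rng.integers(-3000, 10_000))
            pos = int(g["tss"]) + (off if g["strand"] == "+" else -off)
            positions[k] = max(0, pos)
    meth_annotation = pd.DataFrame(
        {"chrom": chroms, "pos": positions},
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # --- expression matrix ---------------------------------------------
    npp = cfg.n_expr_probes_per_gene
    expr_probe_ids = [
        f"EP{i:05d}_{j}" for i in range(cfg.n_genes) for j in range(npp)
    ]
    expr_gene = np.repeat(gene_ids, npp) if cfg.n_genes else np.array([], dtype=object)
    mu_g = rng.normal(8.0, 1.5, cfg.n_genes)
    values = np.repeat(mu_g, npp)[:, None] + np.zeros((len(expr_probe_ids), n))

    atten = np.tile([1.0] + [0.5] * (npp - 1), cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    effect_per_gene = np.zeros(cfg.n_genes)
    for gene, s in deg_sign.items():
        effect_per_gene[gene_pos[gene]] = s * cfg.log2_fc_effect
    values += (np.repeat(effect_per_gene, npp) * atten)[:, None] * case[None, :]

    factors = rng.normal(0.0, cfg.coupling_factor_sd, size=(n_medeg, n))
    for k, (gene, cls) in enumerate(zip(medeg_genes, classes)):
        row = gene_pos[gene] * npp  # designated probe carries the coupling
        values[row] += cfg.coupling_strength * factors[k]

    if cfg.age_effect or cfg.sex_effect:
        values += (
            cfg.age_effect * (age - 43.0) / 10.0
            + cfg.sex_effect * (sex == "M")
        )[None, :]
    # group-independent structure (population stratification / chip batch
    # analogue): dominates the top principal components, which is what
    # makes the PC covariates in the expression model meaningful
    if cfg.n_nuisance_factors and len(expr_probe_ids):
        loadings = rng.normal(
            0.0, cfg.nuisance_loading_sd,
            size=(len(expr_probe_ids), cfg.n_nuisance_factors),
        )
        u = rng.normal(0.0, 1.0, size=(cfg.n_nuisance_factors, n))
        values += loadings @ u
    values += rng.normal(0.0, cfg.expr_noise_sd, size=values.shape)
    expression = pd.DataFrame(
        values, index=pd.Index(expr_probe_ids, name="probe_id"), columns=samples
    )
    expr_annotation = pd.DataFrame(
        {"gene_id": expr_gene, "quality": "perfect"},
        index=pd.Index(expr_probe_ids, name="probe_id"),
    )

    # --- methylation matrix --------------------------------------------
    planted = dmp_sign != 0
    beta0 = np.empty(cfg.n_meth_probes)
    delta = cfg.delta_beta_effect
    for i in np.flatnonzero(planted):
        s = dmp_sign[i]
        lo, hi = (0.3, min(0.7, 0.95 - delta)) if s > 0 else (
            max(0.3, 0.05 + delta), 0.7)
        beta0[i] = rng.uniform(lo, hi) if lo < hi else (lo + hi) / 2
    free = ~planted
    comp = rng.random(free.sum()) < 0.5
    draws = np.where(
        comp, rng.uniform(0.05, 0.25, free.sum()), rng.uniform(0.6, 0.95, free.sum())
    )
    beta0[free] = draws

    mu0 = logit(beta0)
    shift = np.zeros(cfg.n_meth_probes)
    shift[planted] = logit(beta0[planted] + dmp_sign[planted] * delta) - mu0[planted]
    latent = mu0[:, None] + shift[:, None] * case[None, :]
    for k, (gene, cls) in enumerate(zip(medeg_genes, classes)):
        sign_m = -1.0 if cls.startswith("inverse") else 1.0
        latent[k] += sign_m * cfg.coupling_strength * factors[k]
    latent += rng.normal(0.0, cfg.meth_noise_sd, size=latent.shape)
    methylation = pd.DataFrame(
        expit(latent), index=pd.Index(probe_ids, name="probe_id"), columns=samples
    )

    # --- detection p-values --------------------------------------------
    det = rng.uniform(0.0, 0.001, size=(cfg.n_meth_probes, n))
    scatter_idx = np.arange(cfg.n_meth_probes)[scatter_slice]
    failed = rng.choice(scatter_idx, size=n_failed, replace=False) if n_failed else []
    for i in failed:
        det[i, int(rng.integers(n))] = rng.uniform(0.02, 0.1)
    detection = pd.DataFrame(
        det, index=pd.Index(probe_ids, name="probe_id"), columns=samples
    )

    # --- truth ----------------------------------------------------------
    truth = SyntheticTruth(
        deg_effects={g: s * cfg.log2_fc_effect for g, s in deg_sign.items()},
        dmp_effects={
            probe_ids[i]: dmp_sign[i] * delta for i in np.flatnonzero(planted)
        },
        medeg_class=dict(zip(medeg_genes, classes)),
        medeg_meth_probe=medeg_probe,
    )
    truth.validate()

    return Cohort(
        expression=expression,
        methylation=methylation,
        detection=detection,
        metadata=metadata,
        expr_annotation=expr_annotation,
        meth_annotation=meth_annotation,
        gene_models=genes,
        cpg_islands=islands,
        truth=truth,
        config=cfg,
    )


def simulate_feature_matrix(
    n_control: int = 19,
    n_case: int = 18,
    n_informative: int = 6,
    n_features: int = 20,
    effect_size: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample feature matrix for classifier benchmarks.

    Unit-variance Gaussian features; the first ``n_informative`` carry a
    class-mean difference of ``effect_size`` pooled standard deviations,
    the rest are pure noise.  Returns (samples x features DataFrame,
    label array with ``control`` rows first).
    """
    rng = np.random.default_rng(seed)
    n = n_control + n_case
    x = rng.normal(size=(n, n_features))
    x[n_control:, :n_informative] += effect_size
    labels = np.array(["control"] * n_control + ["case"] * n_case)
    features = pd.DataFrame(
        x,
        index=pd.Index(
            [f"NC{i + 1:02d}" for i in range(n_control)]
            + [f"SSc{i + 1:02d}" for i in range(n_case)],
            name="sample_id",
        ),
        columns=[f"g{j:02d}" for j in range(n_features)],
    )
    return features, labels


# ----------------------------------------------------------------------
# on-disk representation (all plain TSV/BED; full-precision round trip)

_FILES = {
    "expression": "expression.tsv",
    "methylation": "methylation.tsv",
    "detection": "detection.tsv",
    "metadata": "metadata.tsv",
    "expr_annotation": "expr_annotation.tsv",
    "meth_annotation": "meth_annotation.tsv",
    "gene_models": "gene_models.tsv",
}


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write every matrix/annotation as TSV (BED3 for islands).

    Values round-trip at full precision through ``read_cohort``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr, fname in _FILES.items():
        path = out / fname
        getattr(cohort, attr).to_csv(path, sep="\t")
        paths[attr] = path
    bed = out / "cpg_islands.bed"
    cohort.cpg_islands.to_csv(bed, sep="\t", header=False, index=False)
    paths["cpg_islands"] = bed

    t = cohort.truth
    probe_gene = {p: g for g, p in t.medeg_meth_probe.items()}
    rows = [
        {
            "id": g,
            "layer": "expr",
            "planted_effect": e,
            "class": t.medeg_class.get(g, "deg"),
            "gene_id": g,
        }
        for g, e in sorted(t.deg_effects.items())
    ] + [
        {
            "id": p,
            "layer": "meth",
            "planted_effect": e,
            "class": t.medeg_class.get(probe_gene.get(p, ""), "dmp"),
            "gene_id": probe_gene.get(p, ""),
        }
        for p, e in sorted(t.dmp_effects.items())
    ]
    truth_path = out / "truth.tsv"
    pd.DataFrame(
        rows, columns=["id", "layer", "planted_effect", "class", "gene_id"]
    ).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


def read_cohort(in_dir) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    d = Path(in_dir)
    frames = {}
    for attr, fname in _FILES.items():
        frames[attr] = pd.read_csv(d / fname, sep="\t", index_col=0)
    frames["metadata"] = frames["metadata"].astype(
        {"age": float, "ild": int}, errors="ignore"
    )
    islands = pd.read_csv(
        d / "cpg_islands.bed", sep="\t", header=None,
        names=["chrom", "start", "end"],
    )
    tt = pd.read_csv(d / "truth.tsv", sep="\t", dtype={"gene_id": str})
    truth = SyntheticTruth()
    for _, r in tt.iterrows():
        if r["layer"] == "expr":
            truth.deg_effects[r["id"]] = float(r["planted_effect"])
            if r["class"] in MEDEG_CLASSES:
                truth.medeg_class[r["id"]] = r["class"]
        else:
            truth.dmp_effects[r["id"]] = float(r["planted_effect"])
            gid = r.get("gene_id", "")
            if isinstance(gid, str) and gid and r["class"] in MEDEG_CLASSES:
                truth.medeg_meth_probe[gid] = r["id"]
    return Cohort(
        expression=frames["expression"],
        methylation=frames["methylation"],
        detection=frames["detection"],
        metadata=frames["metadata"],
        expr_annotation=frames["expr_annotation"],
        meth_annotation=frames["meth_annotation"],
        gene_models=frames["gene_models"],
        cpg_islands=islands,
        truth=truth,
        config=None,
    )
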