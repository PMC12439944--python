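"""Ground-truthed synthetic data emulating LysoIP fractionation and 5EU pulse-chase designs.

The generator produces the three kinds of tables the downstream pipeline
consumes, together with a truth table of per-gene parameters so that every
stage can be tested by parameter recovery:

* a genes x samples count matrix for whole-cell / LysoIP / mock fractions,
  with negative-binomial counting noise and class-structured true lysosomal
  enrichments,
* a spike-in read table whose expected reads are linear in the known
  concentrations, scaled so spike-ins make up a small target fraction of each
  library,
* pulse-chase time courses following single-exponential decay in linear space
  with a background plateau, an nLuc spike row per sample, and mock-IP
  background samples.

Capture distortion is encoded as division by the per-sample capture factor
f_s at simulation time, so that the downstream multiplication by f_s exactly
inverts it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: RNA classes recognized by the generator, in canonical display order.
RNA_CLASSES = (
    "bulk_mRNA",
    "TOP_mRNA",
    "membrane_mRNA",
    "secretory_mRNA",
    "tRNA",
    "Y_RNA",
    "SRP_RNA",
    "vault_RNA",
    "snRNA",
    "mito_RNA",
)

#: Kyte-Doolittle hydropathicity of the amino acid carried by a tRNA.
KYTE_DOOLITTLE = {
    "Ile": 4.5, "Val": 4.2, "Leu": 3.8, "Phe": 2.8, "Cys": 2.5,
    "Met": 1.9, "Ala": 1.8, "Gly": -0.4, "Thr": -0.7, "Ser": -0.8,
    "Trp": -0.9, "Tyr": -1.3, "Pro": -1.6, "His": -3.2, "Glu": -3.5,
    "Gln": -3.5, "Asp": -3.5, "Asn": -3.5, "Lys": -3.9, "Arg": -4.5,
}

_MRNA_CLASSES = {"bulk_mRNA", "TOP_mRNA", "membrane_mRNA", "secretory_mRNA"}

# typical transcript lengths (nt) per class, used as lognormal medians
_CLASS_LENGTH_NT = {
    "bulk_mRNA": 1800, "TOP_mRNA": 1200, "membrane_mRNA": 2500,
    "secretory_mRNA": 2000, "tRNA": 75, "Y_RNA": 100, "SRP_RNA": 300,
    "vault_RNA": 100, "snRNA": 150, "mito_RNA": 1100,
}

# rng stream offsets, one per generator stage (single global seed)
_STREAM_TRANSCRIPTOME = 0
_STREAM_FRACTIONS = 1
_STREAM_PULSECHASE = 2


def _default_proportions() -> Dict[str, float]:
    return {
        "bulk_mRNA": 0.40, "TOP_mRNA": 0.05, "membrane_mRNA": 0.10,
        "secretory_mRNA": 0.10, "tRNA": 0.10, "Y_RNA": 0.02,
        "SRP_RNA": 0.01, "vault_RNA": 0.01, "snRNA": 0.06, "mito_RNA": 0.15,
    }


def _default_multipliers() -> Dict[str, float]:
    # relative lysosomal enrichment per class; nuclear snRNA and mito RNA
    # are depleted, abundant cytosolic ncRNAs strongly enriched
    return {
        "bulk_mRNA": 1.0, "TOP_mRNA": 8.0, "membrane_mRNA": 2.5,
        "secretory_mRNA": 1.8, "tRNA": 4.0, "Y_RNA": 15.0,
        "SRP_RNA": 30.0, "vault_RNA": 12.0, "snRNA": 0.5, "mito_RNA": 0.2,
    }


def _default_spike_concentrations() -> List[float]:
    # 24-point two-fold-per-two-steps ladder spanning ~3.5 orders of magnitude
    return [0.0625 * 2 ** (i / 2.0) for i in range(24)]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults describe the emulated study design: ten RNA classes with
    enrichment multipliers spanning 0.2-30x, whole-cell mean depth of 100
    counts per gene, NB dispersion 0.1, spike-ins targeted at 0.1% of reads,
    pulse-chase timepoints {0, 1, 2, 4, 8, 28} h with two replicates,
    true half-lives log-uniform in [0.5, 30] h, a background plateau at 1e-4
    of the t0 signal, and Torin1 doubling decay rates in WT but not in the
    autophagy-deficient ATG7-KO line.
    """

    n_genes: int = 2000
    class_proportions: Dict[str, float] = field(default_factory=_default_proportions)
    class_enrichment_multipliers: Dict[str, float] = field(default_factory=_default_multipliers)
    baseline_enrichment: float = 1.0
    wc_mean_counts: float = 100.0
    nb_dispersion: float = 0.1
    count_noise: bool = True
    spikein_concentrations: List[float] = field(default_factory=_default_spike_concentrations)
    spikein_target_fraction: float = 0.001
    capture_factors: Optional[Dict[str, float]] = None
    genotype_enrichment_multipliers: Dict[str, Dict[str, float]] = field(default_factory=dict)
    mock_level: float = 0.01
    timepoints_h: List[float] = field(default_factory=lambda: [0.0, 1.0, 2.0, 4.0, 8.0, 28.0])
    true_halflife_range_h: Tuple[float, float] = (0.5, 30.0)
    torin_effect_by_genotype: Dict[str, float] = field(
        default_factory=lambda: {"WT": 2.0, "ATG7_KO": 1.0}
    )
    n_replicates: int = 2
    background_fraction: float = 1e-4
    log2_noise_sd: float = 0.1
    enrichment_jitter_sd: float = 1.0
    abundance_log2_sd: float = 1.0
    hydropathicity_coupling: float = 0.15
    nluc_id: str = "nLuc"
    nluc_scale: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {total!r}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name, value in [
            ("baseline_enrichment", self.baseline_enrichment),
            ("wc_mean_counts", self.wc_mean_counts),
            ("nluc_scale", self.nluc_scale),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for cls, mult in self.class_enrichment_multipliers.items():
            if mult <= 0:
                raise ValueError(f"enrichment multiplier for {cls!r} must be positive")
        if any(c <= 0 for c in self.spikein_concentrations):
            raise ValueError("spike-in concentrations must be strictly positive")
        if not (0.0001 <= self.spikein_target_fraction <= 0.002):
            raise ValueError("spikein_target_fraction must lie in [0.0001, 0.002]")
        if self.nb_dispersion < 0 or self.background_fraction < 0 or self.log2_noise_sd < 0:
            raise ValueError("dispersion, background and noise parameters must be >= 0")
        tp = list(self.timepoints_h)
        if tp != sorted(tp) or (tp and tp[0] != 0):
            raise ValueError("timepoints_h must be sorted ascending and start at 0")
        if any(t < 0 for t in tp):
            raise ValueError("timepoints_h must be nonnegative")
        lo, hi = self.true_halflife_range_h
        if not (0 < lo <= hi):
            raise ValueError("true_halflife_range_h must satisfy 0 < lo <= hi")

    def to_dict(self) -> dict:
        return asdict(self)


def allocate_class_sizes(n_genes: int, proportions: Dict[str, float]) -> Dict[str, int]:
    """Largest-remainder integer allocation of ``n_genes`` across classes.

    Each class gets ``floor(n * p)`` genes; remaining genes go to the classes
    with the largest fractional remainders, ties broken by class name order.
    """
    names = sorted(proportions)
    base = {c: math.floor(n_genes * proportions[c]) for c in names}
    remainder = n_genes - sum(base.values())
    by_frac = sorted(names, key=lambda c: (-(n_genes * proportions[c] - base[c]), c))
    for c in by_frac[:remainder]:
        base[c] += 1
    return base


def simulate_transcriptome(config: SimulationConfig) -> pd.DataFrame:
    """Draw the per-gene truth table.

    Returns one row per gene with its class, true lysosomal enrichment
    ``e_true`` (baseline x class multiplier x lognormal jitter; tRNA
    enrichment additionally coupled to amino-acid hydropathicity), true decay
    rate ``true_k`` (half-life log-uniform over the configured range), model
    constants ``true_c``/``true_z``, relative abundance, TOPscore, and length.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_TRANSCRIPTOME])
    sizes = allocate_class_sizes(config.n_genes, config.class_proportions)

    classes: List[str] = []
    ordered = [c for c in RNA_CLASSES if c in sizes] + [
        c for c in sorted(sizes) if c not in RNA_CLASSES
    ]
    for cls in ordered:
        classes.extend([cls] * sizes[cls])
    n = len(classes)
    cls_arr = np.array(classes, dtype=object)

    gene_id = np.array([f"g{i:05d}" for i in range(n)], dtype=object)
    # draw order is fixed: lengths, abundance, enrichment jitter, half-life,
    # topscore
    length = np.empty(n, dtype=int)
    for cls in ordered:
        mask = cls_arr == cls
        med = _CLASS_LENGTH_NT.get(cls, 1000)
        length[mask] = np.maximum(
            30, np.round(rng.lognormal(math.log(med), 0.3, mask.sum()))
        ).astype(int)

    abundance = 2.0 ** rng.normal(0.0, config.abundance_log2_sd, n)
    jitter = 2.0 ** rng.normal(0.0, config.enrichment_jitter_sd, n)
    mult = np.array(
        [config.class_enrichment_multipliers.get(c, 1.0) for c in classes]
    )
    e_true = config.baseline_enrichment * mult * jitter

    lo, hi = config.true_halflife_range_h
    halflife = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
    true_k = math.log(2) / halflife

    topscore = np.zeros(n)
    is_mrna = np.isin(cls_arr, sorted(_MRNA_CLASSES))
    topscore[is_mrna] = 3.0 * rng.random(is_mrna.sum())
    is_top = cls_arr == "TOP_mRNA"
    topscore[is_top] = 3.0 + 7.0 * rng.random(is_top.sum())

    amino = np.full(n, "", dtype=object)
    hydro = np.full(n, np.nan)
    trna_idx = np.flatnonzero(cls_arr == "tRNA")
    aa_names = sorted(KYTE_DOOLITTLE)
    for j, i in enumerate(trna_idx):
        aa = aa_names[j % len(aa_names)]
        amino[i] = aa
        hydro[i] = KYTE_DOOLITTLE[aa]
    if trna_idx.size:
        e_true[trna_idx] *= 2.0 ** (config.hydropathicity_coupling * hydro[trna_idx])

    truth = pd.DataFrame(
        {
            "gene_id": gene_id,
            "rna_class": cls_arr,
            "length_nt": length,
            "abundance": abundance,
            "e_true": e_true,
            "true_k": true_k,
            "true_c": 1.0,
            "true_z": config.background_fraction,
            "topscore": topscore,
            "trna_amino_acid": amino,
            "hydropathicity": hydro,
        }
    )
    return truth


def default_design(
    genotypes: Sequence[str] = ("tKO",),
    treatments: Sequence[str] = ("none",),
    n_replicates: int = 2,
    capture_factor_wc: float = 1.0,
    capture_factor_lyso: float = 1.0,
    include_mock: bool = False,
) -> pd.DataFrame:
    """Build a sample design table for the fractionation experiment."""
    rows = []
    fractions = [("whole_cell", capture_factor_wc), ("lyso", capture_factor_lyso)]
    if include_mock:
        fractions.append(("mock", 1.0))
    for genotype in genotypes:
        for treatment in treatments:
            for fraction, f_s in fractions:
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{genotype}_{treatment}_{fraction}_r{rep}",
                            "genotype": genotype,
                            "treatment": treatment,
                            "fraction": fraction,
                            "replicate": rep,
                            "capture_factor": float(f_s),
                        }
                    )
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion * mean^2); Poisson when dispersion = 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean).astype(float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def expected_fraction_means(
    truth: pd.DataFrame, design_row: pd.Series, config: SimulationConfig
) -> np.ndarray:
    """Expected gene counts for one sample, before counting noise."""
    f_s = None
    if config.capture_factors is not None:
        f_s = config.capture_factors.get(design_row["sample_id"])
    if f_s is None:
        f_s = design_row.get("capture_factor")
    if f_s is None or not np.isfinite(f_s) or f_s <= 0:
        raise ValueError(
            f"missing or nonpositive capture factor for sample {design_row['sample_id']!r}"
        )
    base = truth["abundance"].to_numpy() * config.wc_mean_counts
    fraction = design_row["fraction"]
    if fraction == "whole_cell":
        mean = base / f_s if f_s != 1.0 else base.copy()
    elif fraction == "lyso":
        gmult = config.genotype_enrichment_multipliers.get(design_row["genotype"], {})
        class_mult = np.array(
            [gmult.get(c, 1.0) for c in truth["rna_class"]], dtype=float
        )
        mean = base * truth["e_true"].to_numpy() * class_mult / f_s
    elif fraction == "mock":
        mean = base * config.mock_level
    else:
        raise ValueError(f"unknown fraction {fraction!r}")
    return mean


def simulate_fraction_counts(
    truth: pd.DataFrame, design: pd.DataFrame, config: SimulationConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the fractionation count matrix and spike-in read table.

    Whole-cell expected counts are proportional to gene abundance; LysoIP
    expected counts additionally scale with the true enrichment and are
    divided by the sample's capture factor (so the downstream f_s
    multiplication inverts the distortion). Spike-in reads are linear in the
    known concentrations; equal spike amounts are added to every sample, with
    the common slope chosen so spike-ins make up the configured fraction of a
    whole-cell library. The constant slope makes noiseless enrichment
    recovery exact rather than merely rank-preserving.
    """
    config.validate()
    required = {"sample_id", "genotype", "treatment", "fraction", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    rng = np.random.default_rng([config.seed, _STREAM_FRACTIONS])

    conc = np.asarray(config.spikein_concentrations, dtype=float)
    spike_ids = [f"spike_{i:02d}" for i in range(len(conc))]
    counts = pd.DataFrame(
        {
            "gene_id": truth["gene_id"],
            "biotype": truth["rna_class"],
            "length_nt": truth["length_nt"],
        }
    )
    spikes = pd.DataFrame({"spike_id": spike_ids, "known_concentration": conc})

    wc_library = truth["abundance"].to_numpy().sum() * config.wc_mean_counts
    slope = (
        config.spikein_target_fraction * wc_library / conc.sum() if conc.size else 0.0
    )
    spike_mean = slope * conc

    gene_cols = {}
    spike_cols = {}
    for _, row in design.iterrows():
        mean = expected_fraction_means(truth, row, config)
        if config.count_noise:
            gene_cols[row["sample_id"]] = _nb_draw(rng, mean, config.nb_dispersion)
            # spikes are a common technical pool added to every tube: no
            # biological overdispersion, Poisson counting noise only
            spike_cols[row["sample_id"]] = _nb_draw(rng, spike_mean, 0.0)
        else:
            gene_cols[row["sample_id"]] = mean
            spike_cols[row["sample_id"]] = spike_mean
    counts = pd.concat([counts, pd.DataFrame(gene_cols)], axis=1)
    spikes = pd.concat([spikes, pd.DataFrame(spike_cols)], axis=1)
    return counts, spikes


def simulate_pulse_chase(
    truth: pd.DataFrame, config: SimulationConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw 5EU pulse-chase time courses and the mock-IP background table.

    For each gene, genotype, treatment and replicate the expected signal at
    chase time ``x`` is ``C * exp(-k x) + background_fraction`` on the
    spike-normalized scale (true C = 1); Torin1 multiplies ``k`` by the
    genotype's configured effect and shares C with the untreated series of
    the same replicate. Emitted counts are the signal scaled by the per-sample
    nLuc level (an nLuc row is included per sample) with multiplicative
    lognormal noise of ``log2_noise_sd``. The mock table carries four
    background samples and the spike-normalized t0 reads used for the
    background term z.
    """
    config.validate()
    if any(t < 0 for t in config.timepoints_h):
        raise ValueError("timepoints must be nonnegative")
    rng = np.random.default_rng([config.seed, _STREAM_PULSECHASE])
    genotypes = sorted(config.torin_effect_by_genotype)
    timepoints = np.asarray(config.timepoints_h, dtype=float)
    n = len(truth)
    sd = config.log2_noise_sd

    t0_reads = truth["abundance"].to_numpy() * 1e3
    mock_jitter = 2.0 ** rng.normal(0.0, sd, (n, 4)) if sd > 0 else np.ones((n, 4))
    mock_vals = config.background_fraction * t0_reads[:, None] * mock_jitter
    mock = pd.DataFrame(
        {
            "gene_id": truth["gene_id"],
            "t0_reads": t0_reads,
            **{f"mock_{j + 1}": mock_vals[:, j] for j in range(4)},
        }
    )

    k_true = truth["true_k"].to_numpy()
    c_true = truth["true_c"].to_numpy()
    frames = []

    def sample_frame(genotype, treatment, rep, t, count, nluc_count):
        return pd.DataFrame(
            {
                "gene_id": np.append(truth["gene_id"].to_numpy(), config.nluc_id),
                "genotype": genotype,
                "treatment": treatment,
                "replicate": rep,
                "time_h": t,
                "count": np.append(count, nluc_count),
            }
        )

    # treatment starts at the beginning of the chase, so within a replicate
    # the t = 0 sample precedes arm divergence and is shared by both arms
    for genotype in genotypes:
        torin_mult = config.torin_effect_by_genotype[genotype]
        for rep in range(1, config.n_replicates + 1):
            depth0 = 2.0 ** rng.normal(0.0, sd) if sd > 0 else 1.0
            noise0 = 2.0 ** rng.normal(0.0, sd, n) if sd > 0 else 1.0
            signal0 = c_true + config.background_fraction
            count0 = signal0 * noise0 * config.nluc_scale * depth0
            nluc0 = config.nluc_scale * depth0
            for treatment in ("none", "torin1"):
                k_eff = k_true * (torin_mult if treatment == "torin1" else 1.0)
                for t in timepoints:
                    if t == 0:
                        frames.append(
                            sample_frame(genotype, treatment, rep, t, count0, nluc0)
                        )
                        continue
                    depth = 2.0 ** rng.normal(0.0, sd) if sd > 0 else 1.0
                    signal = c_true * np.exp(-k_eff * t) + config.background_fraction
                    noise = 2.0 ** rng.normal(0.0, sd, n) if sd > 0 else 1.0
                    count = signal * noise * config.nluc_scale * depth
                    frames.append(
                        sample_frame(
                            genotype, treatment, rep, t, count, config.nluc_scale * depth
                        )
                    )
    timecourse = pd.concat(frames, ignore_index=True)
    return timecourse, mock


def annotation_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Derive the gene annotation table the enrichment stage consumes."""
    localization = truth["rna_class"].map(
        {
            "membrane_mRNA": "membrane",
            "secretory_mRNA": "secretory",
            "mito_RNA": "mitochondrial",
        }
    ).fillna("other")
    with np.errstate(divide="ignore"):
        agg_halflife = np.where(
            truth["true_k"] > 0, math.log(2) / truth["true_k"], np.inf
        )
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"],
            "rna_class": truth["rna_class"],
            "topscore": truth["topscore"],
            "localization": localization,
            "aggregate_halflife_metric": agg_halflife,
            "trna_amino_acid": truth["trna_amino_acid"],
            "hydropathicity": truth["hydropathicity"],
        }
    )
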