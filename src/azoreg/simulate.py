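"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of (config, seed): the same config run
twice yields byte-identical output. Default parameters emulate the study
conditions the pipeline was designed around: a heterogeneous compendium of
50 datasets totalling 462 samples (~89% K-12 substrains) with condition
effects on the focal gene and a 10-gene co-expressed module planted in 10
datasets; a 4320-clone arrayed transposon library with small planted
reduced/increased decolorizer classes; triplicate Ct tables with planted
log2 fold changes; and a toy annotated genome with junction reads planted
at known insertion points.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .compendium import (
    CONDITION_KEYS,
    Compendium,
    ExpressionDataset,
    bin_label,
    to_percentile_ranks,
)
from .mapping import TN5_MOSAIC_END, revcomp


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# truth bundle
# ---------------------------------------------------------------------------


@dataclass
class TruthBundle:
    """Planted ground truth of one simulation (fields unused by a given
    generator stay None)."""

    condition_effects: dict[str, float] | None = None
    modules: list[dict] | None = None  # {genes, r, dataset_ids}
    strain_class: dict[str, str] | None = None
    true_decolorization: dict[str, float] | None = None
    log2_folds: dict[str, float] | None = None  # "gene|condition" -> log2 fc
    insertions: list[dict] | None = None  # {read_id, position, strand, gene}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthBundle":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# expression compendium
# ---------------------------------------------------------------------------

#: The ten-gene module planted by default, named after oxidoreductase /
#: flavoprotein partners typical of an azoreductase's co-expression context.
DEFAULT_MODULE_GENES = (
    "tesA", "pspE", "nfsA", "nfsB", "yieF", "fdnG", "yciK", "fpr", "rutF", "melA",
)

K12_STRAINS = ("K-12 MG1655", "K-12 BW25113", "K-12 W3110")
OTHER_STRAINS = ("BL21(DE3)", "B REL606", "O157:H7 Sakai", "CFT073")
MEDIA = ("LB", "M9 minimal", "MOPS minimal", "TSB")
PHASES = ("lag", "log", "stationary")
OD_POOL = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0, 1.5, 2.0)
GLUCOSE_POOL = (0.02, 0.1, 0.2, 0.4, 0.5)
RPM_POOL = (0, 60, 150, 200, 250, 300)
TEMP_POOL = (25, 30, 37)


def default_condition_effects() -> dict[str, float]:
    """Percentile-point shifts on the focal gene, keyed ``field=category``.

    Directions mirror the conditions under which the focal azoreductase gene
    is reported high (mid culture density, log phase, minimal media, high
    glucose, slow agitation, 25-30 C) or low (their opposites).
    """
    return {
        "od600=0.4-0.7": 12.0,
        "od600=>0.7": -8.0,
        "growth_phase=log": 12.0,
        "growth_phase=stationary": -10.0,
        "medium=M9 minimal": 8.0,
        "medium=MOPS minimal": 8.0,
        "medium=TSB": -10.0,
        "glucose_pct=>=0.5%": 10.0,
        "glucose_pct=0.1-0.4%": -8.0,
        "agitation_rpm=<=60 rpm": 10.0,
        "agitation_rpm=200-300 rpm": -10.0,
        "temperature_C=25-30 C": 10.0,
        "temperature_C=37 C": -10.0,
    }


@dataclass(frozen=True)
class PlantedModule:
    genes: tuple[str, ...]
    r: float
    n_datasets: int = 10

    def __post_init__(self):
        if not 0 < self.r <= 1:
            raise ConfigError(f"planted r must be in (0, 1], got {self.r}")


@dataclass
class CompendiumSimConfig:
    n_datasets: int = 50
    n_genes: int = 4000
    samples_per_dataset: tuple[int, int] = (4, 20)
    total_samples: int | None = 462
    focal_gene: str = "azoR"
    condition_effects: Mapping[str, float] = field(default_factory=default_condition_effects)
    planted_modules: tuple[PlantedModule, ...] = (
        PlantedModule(DEFAULT_MODULE_GENES, 0.95, 10),
    )
    noise_sd: float = 8.0  # percentile points on the focal gene's target rank
    k12_fraction: float = 411 / 462
    metadata_omission_rate: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.n_datasets < 1:
            raise ConfigError("n_datasets must be >= 1")
        lo, hi = self.samples_per_dataset
        if not 1 <= lo <= hi:
            raise ConfigError("invalid samples_per_dataset range")
        if self.total_samples is not None and not (
            self.n_datasets * lo <= self.total_samples <= self.n_datasets * hi
        ):
            raise ConfigError("total_samples unreachable from samples_per_dataset range")
        planted = [g for m in self.planted_modules for g in m.genes]
        if len(set(planted)) != len(planted):
            raise ConfigError("planted module genes overlap")
        if self.focal_gene in planted:
            raise ConfigError("focal gene cannot be a planted module member")
        if 1 + len(planted) > self.n_genes:
            raise ConfigError("planted module genes exceed the gene universe")


def _sample_counts(cfg: CompendiumSimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.samples_per_dataset
    counts = rng.integers(lo, hi + 1, size=cfg.n_datasets)
    if cfg.total_samples is not None:
        while counts.sum() > cfg.total_samples:
            i = rng.integers(cfg.n_datasets)
            if counts[i] > lo:
                counts[i] -= 1
        while counts.sum() < cfg.total_samples:
            i = rng.integers(cfg.n_datasets)
            if counts[i] < hi:
                counts[i] += 1
    return counts


def gen_compendium(cfg: CompendiumSimConfig) -> tuple[Compendium, TruthBundle]:
    """Generate a percentile-rank compendium with planted effects.

    Per dataset, a latent standard-normal matrix is built; the focal gene's
    latent profile encodes a target percentile (50 + condition shifts +
    noise, clamped), module genes copy the focal latent profile at the
    planted correlation, and every column is then converted to percentile
    ranks, so rank-scale validity is preserved by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    module_genes = [g for m in cfg.planted_modules for g in m.genes]
    n_bg = cfg.n_genes - 1 - len(module_genes)
    universe = [cfg.focal_gene] + module_genes + [f"g{i:05d}" for i in range(n_bg)]

    counts = _sample_counts(cfg, rng)
    dataset_ids = [f"DS{i:03d}" for i in range(cfg.n_datasets)]

    # choose the datasets each module is planted in
    module_sets: list[tuple[PlantedModule, set[str]]] = []
    truth_modules = []
    for m in cfg.planted_modules:
        if m.n_datasets > cfg.n_datasets:
            raise ConfigError("module planted in more datasets than exist")
        chosen = sorted(rng.choice(cfg.n_datasets, size=m.n_datasets, replace=False))
        ids = {dataset_ids[i] for i in chosen}
        module_sets.append((m, ids))
        truth_modules.append({"genes": list(m.genes), "r": m.r,
                              "dataset_ids": sorted(ids)})

    # strain labels: an exact K-12 count across the whole compendium
    total = int(counts.sum())
    n_k12 = int(round(cfg.k12_fraction * total))
    strains = np.concatenate([
        rng.choice(K12_STRAINS, size=n_k12),
        rng.choice(OTHER_STRAINS, size=total - n_k12),
    ])
    strains = strains[rng.permutation(total)]

    meta_rows = []
    datasets = []
    s_idx = 0
    for d_i, ds_id in enumerate(dataset_ids):
        n_s = int(counts[d_i])
        sample_ids = [f"{ds_id}_s{j:02d}" for j in range(n_s)]
        # metadata heterogeneity: the dataset omits a random subset of
        # condition fields entirely (missing, not defaulted)
        present = [k for k in CONDITION_KEYS if rng.random() >= cfg.metadata_omission_rate]
        if not present:
            present = [CONDITION_KEYS[int(rng.integers(len(CONDITION_KEYS)))]]
        shifts = np.zeros(n_s)
        for j, s_id in enumerate(sample_ids):
            row: dict = {"sample_id": s_id, "dataset_id": ds_id,
                         "strain": str(strains[s_idx + j])}
            values = {
                "od600": float(rng.choice(OD_POOL)),
                "growth_phase": str(rng.choice(PHASES)),
                "medium": str(rng.choice(MEDIA)),
                "glucose_pct": float(rng.choice(GLUCOSE_POOL)),
                "agitation_rpm": float(rng.choice(RPM_POOL)),
                "temperature_C": float(rng.choice(TEMP_POOL)),
            }
            for k in CONDITION_KEYS:
                if k in present:
                    row[k] = values[k]
                    lab = bin_label(k, values[k])
                    if lab is not None:
                        shifts[j] += cfg.condition_effects.get(f"{k}={lab}", 0.0)
                else:
                    row[k] = None
            meta_rows.append(row)
        s_idx += n_s

        target_pct = np.clip(50.0 + shifts + rng.normal(0, cfg.noise_sd, n_s), 0.5, 99.5)
        z_focal = norm.ppf(target_pct / 100.0)
        # standardize the focal latent before mixing, so module genes attain
        # the target correlation r rather than r scaled by sd(z_focal)
        z_sd = float(z_focal.std())
        z_std = (z_focal - z_focal.mean()) / z_sd if z_sd > 0 else z_focal
        raw = np.empty((cfg.n_genes, n_s))
        raw[0] = z_focal
        r_i = 1
        for m, ids in module_sets:
            for _ in m.genes:
                eps = rng.standard_normal(n_s)
                if ds_id in ids:
                    raw[r_i] = m.r * z_std + math.sqrt(1 - m.r**2) * eps
                else:
                    raw[r_i] = eps
                r_i += 1
        raw[r_i:] = rng.standard_normal((cfg.n_genes - r_i, n_s))
        ranks = to_percentile_ranks(
            pd.DataFrame(raw, index=universe, columns=sample_ids)
        )
        datasets.append(ExpressionDataset(ds_id, ranks))

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = TruthBundle(
        condition_effects=dict(cfg.condition_effects), modules=truth_modules
    )
    return Compendium(datasets, metadata), truth


# ---------------------------------------------------------------------------
# plate screen
# ---------------------------------------------------------------------------

WT_STRAIN = "WT"
KO_CONTROL_STRAIN = "dAzoR"  # knockout control: near-zero decolorization

_WELLS_96 = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]


@dataclass
class ScreenSimConfig:
    n_mutants: int = 4320
    wells_per_plate: int = 96
    wt_decol_mean: float = 60.0  # % decolorization of the wild type
    wt_decol_sd: float = 4.0  # per-well measurement noise, percentage points
    effect_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"neutral": 1.0, "reduced": 0.5, "increased": 1.3}
    )
    # planted non-neutral fraction ~0.5% of the library: a 4320-clone screen
    # then yields confirmed-hit counts of the same order as a real screen
    class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"neutral": 0.995, "reduced": 0.0035, "increased": 0.0015}
    )
    initial_abs_mean: float = 1.0
    initial_abs_sd: float = 0.02
    wt_wells_per_plate: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_mutants <= 0:
            raise ConfigError("n_mutants must be > 0")
        if any(m <= 0 for m in self.effect_multipliers.values()):
            raise ConfigError("effect multipliers must be > 0")
        if set(self.class_probs) - set(self.effect_multipliers):
            raise ConfigError("class_probs has classes without multipliers")
        if abs(sum(self.class_probs.values()) - 1) > 1e-9:
            raise ConfigError("class_probs must sum to 1")
        if self.wells_per_plate != 96:
            raise ConfigError("only 96-well plates are supported")


def _measure_wells(true_decol: np.ndarray, cfg: ScreenSimConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    a0 = np.maximum(rng.normal(cfg.initial_abs_mean, cfg.initial_abs_sd,
                               true_decol.size), 0.05)
    obs = true_decol + rng.normal(0, cfg.wt_decol_sd, true_decol.size)
    a1 = a0 * (1 - obs / 100.0)
    return a0, a1


def gen_screen(cfg: ScreenSimConfig) -> tuple[pd.DataFrame, TruthBundle]:
    """Arrayed single-measurement screen plates with planted effect classes.

    Each plate carries ``wt_wells_per_plate`` wild-type wells plus one
    knockout control well (a strain with near-zero decolorization, the
    assay's negative control); the remaining wells hold mutants.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = sorted(cfg.class_probs)
    probs = np.array([cfg.class_probs[c] for c in classes])
    mutant_ids = [f"M{i:04d}" for i in range(1, cfg.n_mutants + 1)]
    assigned = rng.choice(len(classes), size=cfg.n_mutants, p=probs)
    strain_class = {m: classes[a] for m, a in zip(mutant_ids, assigned)}
    true_decol = {
        m: cfg.wt_decol_mean * cfg.effect_multipliers[strain_class[m]]
        for m in mutant_ids
    }
    true_decol[WT_STRAIN] = cfg.wt_decol_mean
    true_decol[KO_CONTROL_STRAIN] = 2.0  # residual abiotic fading

    mutants_per_plate = cfg.wells_per_plate - cfg.wt_wells_per_plate - 1
    rows = []
    i = 0
    plate_no = 0
    while i < cfg.n_mutants:
        plate_no += 1
        plate_id = f"P{plate_no:03d}"
        strains = [WT_STRAIN] * cfg.wt_wells_per_plate + [KO_CONTROL_STRAIN]
        strains += mutant_ids[i : i + mutants_per_plate]
        i += mutants_per_plate
        td = np.array([true_decol[s] for s in strains])
        a0, a1 = _measure_wells(td, cfg, rng)
        for w, s, x0, x1 in zip(_WELLS_96, strains, a0, a1):
            rows.append({"plate": plate_id, "well": w, "strain": s,
                         "A450_0h": round(float(x0), 4), "A450_16h": round(float(x1), 4)})
    plates = pd.DataFrame(rows, columns=["plate", "well", "strain", "A450_0h", "A450_16h"])
    truth = TruthBundle(strain_class=strain_class,
                        true_decolorization={k: float(v) for k, v in true_decol.items()})
    return plates, truth


def gen_retest(
    cfg: ScreenSimConfig,
    truth: TruthBundle,
    strains: Sequence[str],
    n_measurements: int = 6,
    wt_n_measurements: int = 24,
    seed: int = 1,
) -> pd.DataFrame:
    """Replicate retest measurements (decol_pct) for selected strains + WT.

    Defaults to six measurements per strain (two experiments of three
    replicates each). The wild type gets more wells (it is the shared
    reference on every retest plate), so the normalization denominator is
    estimated much more precisely than any single candidate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in list(strains) + [WT_STRAIN]:
        n = wt_n_measurements if s == WT_STRAIN else n_measurements
        td = np.full(n, truth.true_decolorization[s])
        a0, a1 = _measure_wells(td, cfg, rng)
        for rep, (x0, x1) in enumerate(zip(a0, a1), start=1):
            rows.append({"strain": s, "replicate": rep,
                         "decol_pct": (x0 - x1) / x0 * 100.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass
class QpcrSimConfig:
    genes: tuple[str, ...] = ("azoR", "arsC", "relA", "plsY", "trmM", "ihfB")
    conditions: tuple[str, ...] = ("control", "MR_5mg_L", "MR_50mg_L")
    replicates: int = 3
    baseline_ct: float = 20.0
    planted_log2_fold: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("azoR", "MR_5mg_L"): 2.0,
            ("azoR", "MR_50mg_L"): 2.5,
            ("arsC", "MR_5mg_L"): 1.5,
            ("relA", "MR_5mg_L"): 1.2,
            ("trmM", "MR_5mg_L"): 0.8,
        }
    )
    ct_noise_sd: float = 0.2
    reference_gene: str = "ihfB"
    control_condition: str = "control"
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        if self.reference_gene not in self.genes:
            raise ConfigError("reference gene must be in genes")
        for (g, c), f in self.planted_log2_fold.items():
            if g == self.reference_gene and f != 0:
                raise ConfigError(
                    "reference gene cannot carry a planted fold "
                    "(violates the reference-gene assumption)"
                )
            if c == self.control_condition and f != 0:
                raise ConfigError("control condition folds are 1 by definition")
            if g not in self.genes or c not in self.conditions:
                raise ConfigError(f"planted fold references unknown ({g!r}, {c!r})")


def gen_qpcr(cfg: QpcrSimConfig) -> tuple[pd.DataFrame, TruthBundle]:
    """Ct table with planted log2 fold changes.

    Ct(gene, condition, rep) = baseline(gene) - planted_log2_fold + noise;
    a doubling of transcript lowers Ct by one cycle. Per-gene baselines are
    jittered around ``baseline_ct`` so genes are distinguishable.
    """
    rng = np.random.default_rng(cfg.seed)
    baselines = {g: cfg.baseline_ct + float(rng.uniform(-3, 3)) for g in cfg.genes}
    rows = []
    for g in cfg.genes:
        for c in cfg.conditions:
            fold = float(cfg.planted_log2_fold.get((g, c), 0.0))
            for rep in range(1, cfg.replicates + 1):
                ct = baselines[g] - fold + float(rng.normal(0, cfg.ct_noise_sd))
                if ct <= 0:
                    raise ConfigError("generated Ct <= 0; raise baseline_ct")
                rows.append({"gene": g, "condition": c, "replicate": rep,
                             "ct": round(ct, 4)})
    truth = TruthBundle(log2_folds={f"{g}|{c}": float(v)
                                    for (g, c), v in cfg.planted_log2_fold.items()})
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"]), truth


# ---------------------------------------------------------------------------
# reference genome + junction reads
# ---------------------------------------------------------------------------


@dataclass
class MapSimConfig:
    genome_length: int = 50_000
    n_genes: int = 40
    n_insertions: int = 24
    read_length: int = 400
    transposon_end_seq: str = TN5_MOSAIC_END
    ambiguous_rate: float = 0.0
    gene_names: tuple[str, ...] = ()  # optional names for the first genes
    gene_length_range: tuple[int, int] = (300, 1200)
    seed: int = 0

    def __post_init__(self):
        if self.read_length >= self.genome_length:
            raise ConfigError("read_length must be < genome_length")
        if not 0 <= self.ambiguous_rate < 1:
            raise ConfigError("ambiguous_rate must be in [0, 1)")
        if len(self.gene_names) > self.n_genes:
            raise ConfigError("more gene_names than n_genes")


@dataclass
class MapSimData:
    genome: str
    annotations: pd.DataFrame  # gene, start, end, strand (1-based inclusive)
    reads: list[tuple[str, str]]  # (read_id, sequence)


def _place_genes(cfg: MapSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = cfg.gene_length_range
    names = list(cfg.gene_names) + [
        f"gene{i:03d}" for i in range(len(cfg.gene_names), cfg.n_genes)
    ]
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    free = cfg.genome_length - int(lengths.sum())
    if free < 0:
        raise ConfigError("could not place non-overlapping gene intervals")
    # distribute the free space into inter-gene gaps; genes may touch but
    # never overlap, and placement always succeeds when the lengths fit
    gaps = rng.multinomial(free, np.full(cfg.n_genes + 1, 1 / (cfg.n_genes + 1)))
    placed: list[tuple[int, int]] = []
    cursor = 0
    for g, length in zip(gaps[:-1], lengths):
        start = cursor + int(g)
        placed.append((start, start + int(length)))  # 0-based half-open
        cursor = start + int(length)
    return pd.DataFrame(
        {
            "gene": names,
            "start": [s + 1 for s, _ in placed],
            "end": [e for _, e in placed],
            "strand": [str(rng.choice(["+", "-"])) for _ in placed],
        }
    )


def gen_reference_and_reads(cfg: MapSimConfig) -> tuple[MapSimData, TruthBundle]:
    """Toy genome, gene annotation and transposon-junction reads.

    Each read is the transposon end sequence followed by the genomic flank
    that starts at the true insertion point, on a random strand; ambiguous
    bases ('N') are injected into the flank at ``ambiguous_rate``. The
    insertion position (1-based, first flank base) and interrupted gene are
    recorded as truth.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = "".join(rng.choice(list("ACGT"), size=cfg.genome_length))
    ann = _place_genes(cfg, rng)
    flank_len = cfg.read_length - len(cfg.transposon_end_seq)
    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    for i in range(cfg.n_insertions):
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            pos0 = int(rng.integers(0, cfg.genome_length - flank_len))
            flank = genome[pos0 : pos0 + flank_len]
        else:
            pos0 = int(rng.integers(flank_len - 1, cfg.genome_length))
            flank = revcomp(genome[pos0 - flank_len + 1 : pos0 + 1])
        if cfg.ambiguous_rate > 0:
            mask = rng.random(flank_len) < cfg.ambiguous_rate
            flank = "".join("N" if m else b for b, m in zip(flank, mask))
        read_id = f"read{i:03d}"
        reads.append((read_id, cfg.transposon_end_seq + flank))
        pos1 = pos0 + 1
        hit = ann[(ann["start"] <= pos1) & (ann["end"] >= pos1)]
        truth_rows.append({
            "read_id": read_id,
            "position": pos1,
            "strand": strand,
            "gene": str(hit.iloc[0]["gene"]) if not hit.empty else "intergenic",
        })
    return MapSimData(genome, ann, reads), TruthBundle(insertions=truth_rows)
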