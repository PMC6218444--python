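"""Synthetic MeRIP-seq data with a planted, condition-specific methylome.

The generator emulates the experimental design the analysis assumes:
poly(A) RNA chemically fragmented to ~100 nt, antibody IP of fragments
carrying m6A, matched input libraries from the same fragment pool,
single-end 50-bp reads, two replicates in each of three conditions
(parental, TKI-resistant, resensitized).  Resistance is modelled as
demethylase-driven loss of methylation at a random subset of parental
m6A sites; resensitization restores the parental methylome.

Candidate m6A sites are planted GGACU motifs; each is methylated in the
parental condition with probability ``methylation_rate`` (level 1.0).
IP libraries capture a fragment with weight
``1 + (ip_enrichment - 1) * level`` when it covers a methylated site,
so the IP/input read-count ratio inside a fully methylated site
approaches ``ip_enrichment`` over a flat background.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .models import CONDITIONS, DecayCourse, ReadLibrary, TranscriptModel

DRACH_MOTIFS = ("GGACU", "GAACU", "AAACU", "AGACU")
_PLANTED_MOTIF = "GGACU"
_SITE_SLOT_SPACING = 450  # min distance between planted sites, keeps peaks separable
_SITE_JITTER = 100
_BASE_LOG2_EXPR = 8.0  # arbitrary microarray-scale intensity offset


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 100
    length_range: tuple[int, int] = (500, 3000)
    noncoding_fraction: float = 0.1
    sites_per_kb: float = 1.0
    methylation_rate: float = 0.5
    demethylation_fraction: float = 0.5
    ip_enrichment: float = 8.0
    fragment_length: int = 100   # chemical fragmentation size
    read_length: int = 50        # single-end read length
    depth_per_library: int = 500_000
    replicates: int = 2
    dispersion: float = 0.05     # NB gene-level overdispersion
    n_de_genes: int = 20
    de_fold: float = 2.0
    expression_noise_sd: float = 0.2  # log2 units
    array_replicates: int = 4    # expression-matrix samples per group
    resensitized_restoration: float = 1.0  # 1 = full return to parental methylome
    ct_noise_sd: float = 0.0     # qPCR cycle noise for decay courses
    qpcr_replicates: int = 3     # technical wells per timepoint (standard triplicate)

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("noncoding_fraction", "methylation_rate",
                     "demethylation_fraction", "resensitized_restoration"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ip_enrichment < 1:
            raise ValueError("ip_enrichment must be >= 1")
        if self.depth_per_library < 0:
            raise ValueError("depth_per_library must be >= 0")
        if self.de_fold <= 0:
            raise ValueError("de_fold must be > 0")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must be <= n_genes")
        lo, hi = self.length_range
        if not 0 < lo <= hi:
            raise ValueError("length_range must satisfy 0 < lo <= hi")


# demo actinomycin-D chase: stabilized transcripts in the resistant state
DEFAULT_DECAY_GENES = (
    ("MERTK_parental", 3.0),
    ("MERTK_resistant", 8.0),
    ("BCL2_parental", 4.0),
    ("BCL2_resistant", 10.0),
    ("STABLE_control", np.inf),
)
DEFAULT_DECAY_TIMEPOINTS = (0.0, 2.0, 4.0, 6.0, 8.0)


@dataclass
class SimulatedDataset:
    """All artifacts of one simulated study, ready for the pipeline."""

    config: SimulationConfig
    models: dict[str, TranscriptModel]
    methylome: pd.DataFrame          # transcript_id, site_position, condition, methylation_level
    libraries: list[ReadLibrary]
    expression: pd.DataFrame         # genes x samples, log2 scale
    expression_groups: dict[str, str]
    expression_truth: pd.DataFrame
    decay_courses: list[DecayCourse] = field(default_factory=list)
    decay_truth: pd.DataFrame | None = None


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def simulate_transcriptome(config: SimulationConfig) -> dict[str, TranscriptModel]:
    """Random transcript models with sequences and planted GGACU sites.

    Coding transcripts are partitioned ~10/60/30% into 5'UTR/CDS/3'UTR.
    """
    config.validate()
    rng = _rng(config, 1)
    models: dict[str, TranscriptModel] = {}
    for i in range(config.n_genes):
        tid = f"tx{i:04d}"
        gid = f"gene{i:04d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        noncoding = rng.random() < config.noncoding_fraction
        seq = rng.choice(list("ACGU"), size=length)
        planted = _candidate_site_positions(length, config, rng)
        for pos in planted:
            seq[pos : pos + len(_PLANTED_MOTIF)] = list(_PLANTED_MOTIF)
        _scrub_unplanted_motifs(seq, planted)
        if noncoding:
            cds_start = cds_end = None
        else:
            cds_start = int(round(0.10 * length))
            cds_end = int(round(0.70 * length))
        models[tid] = TranscriptModel(
            gene_id=gid,
            transcript_id=tid,
            length=length,
            cds_start=cds_start,
            cds_end=cds_end,
            sequence="".join(seq),
        )
    return models


def _scrub_unplanted_motifs(seq: np.ndarray, planted: Sequence[int]) -> None:
    """Mutate chance GGACU occurrences so the planted set is the truth.

    Candidate m6A sites must be exactly the planted ones; a random
    background motif would otherwise enter the methylome at an
    uncontrolled position.  The first G of each stray occurrence is
    flipped to C; rescan until clean (a flip can create a new upstream
    occurrence only finitely often).
    """
    text = "".join(seq)
    planted_set = set(planted)
    for _ in range(10):
        dirty = False
        start = text.find(_PLANTED_MOTIF)
        while start != -1:
            if start not in planted_set:
                seq[start] = "C"
                dirty = True
            start = text.find(_PLANTED_MOTIF, start + 1)
        if not dirty:
            return
        text = "".join(seq)


def _candidate_site_positions(
    length: int, config: SimulationConfig, rng: np.random.Generator
) -> list[int]:
    # keep sites >= 50 nt from the 5' end and >= 55 nt from the 3' end so
    # fragments covering a site always fit inside the transcript
    slots = np.arange(50, length - 160, _SITE_SLOT_SPACING)
    if slots.size == 0:
        return []
    n = min(int(rng.poisson(config.sites_per_kb * length / 1000.0)), slots.size)
    if n == 0:
        return []
    chosen = rng.choice(slots.size, size=n, replace=False)
    return sorted(
        int(slots[k] + rng.integers(0, _SITE_JITTER + 1)) for k in chosen
    )


def find_planted_sites(models: Mapping[str, TranscriptModel]) -> pd.DataFrame:
    """Locate planted GGACU occurrences (candidate m6A sites) per transcript."""
    rows = []
    for tid in sorted(models):
        m = models[tid]
        if m.sequence is None:
            raise ValueError(f"{tid}: model has no sequence")
        start = m.sequence.find(_PLANTED_MOTIF)
        while start != -1:
            rows.append((tid, m.gene_id, start))
            start = m.sequence.find(_PLANTED_MOTIF, start + 1)
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "site_position"])


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def simulate_methylome(
    models: Mapping[str, TranscriptModel], config: SimulationConfig
) -> pd.DataFrame:
    """Per-site, per-condition methylation levels.

    Parental: each candidate site methylated (level 1.0) with probability
    ``methylation_rate``.  Resistant: a ``demethylation_fraction`` subset
    of methylated sites drops to 0.  Resensitized: parental levels scaled
    back by ``resensitized_restoration`` at the demethylated sites.
    """
    config.validate()
    sites = find_planted_sites(models)
    rng = _rng(config, 2)
    n = len(sites)
    methylated = rng.random(n) < config.methylation_rate
    parental = np.where(methylated, 1.0, 0.0)
    demeth = methylated & (rng.random(n) < config.demethylation_fraction)
    resistant = np.where(demeth, 0.0, parental)
    resensitized = np.where(
        demeth, config.resensitized_restoration * parental, parental
    )
    frames = []
    for cond, levels in zip(CONDITIONS, (parental, resistant, resensitized)):
        df = sites.copy()
        df["condition"] = cond
        df["methylation_level"] = levels
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def methylome_site_levels(
    methylome: pd.DataFrame, condition: str
) -> dict[str, list[tuple[int, float]]]:
    """Per-transcript (site_position, level) lists for one condition."""
    sub = methylome[methylome["condition"] == condition]
    out: dict[str, list[tuple[int, float]]] = {}
    for tid, grp in sub.groupby("transcript_id"):
        out[str(tid)] = list(
            zip(grp["site_position"].astype(int), grp["methylation_level"])
        )
    return out


def demethylated_sites(methylome: pd.DataFrame) -> pd.DataFrame:
    """Sites methylated in parental but not in resistant (the planted losses)."""
    par = methylome[methylome["condition"] == "parental"].set_index(
        ["transcript_id", "site_position"]
    )["methylation_level"]
    res = methylome[methylome["condition"] == "resistant"].set_index(
        ["transcript_id", "site_position"]
    )["methylation_level"]
    lost = par[(par > 0) & (res.reindex(par.index) == 0)]
    return lost.reset_index()[["transcript_id", "site_position"]]


# ---------------------------------------------------------------------------
# Read libraries
# ---------------------------------------------------------------------------

def gene_base_expression(config: SimulationConfig) -> pd.Series:
    """Log-normal relative expression across genes (sd = 1 log2 unit)."""
    rng = _rng(config, 3)
    tids = [f"tx{i:04d}" for i in range(config.n_genes)]
    return pd.Series(np.exp2(rng.normal(0.0, 1.0, config.n_genes)), index=tids)


def _ip_weights(
    length: int, sites: Sequence[tuple[int, float]], config: SimulationConfig
) -> np.ndarray:
    """IP capture weight per fragment start position on one transcript."""
    s_max = max(length - config.fragment_length, 0)
    w = np.ones(s_max + 1)
    for pos, level in sites:
        if level <= 0:
            continue
        a_pos = pos + 2  # the methylated A of the planted GGACU
        lo = max(0, a_pos - config.fragment_length + 1)
        hi = min(a_pos, s_max)
        if lo <= hi:
            np.maximum(
                w[lo : hi + 1],
                1.0 + (config.ip_enrichment - 1.0) * level,
                out=w[lo : hi + 1],
            )
    return w


def simulate_libraries(
    models: Mapping[str, TranscriptModel],
    methylome: pd.DataFrame,
    config: SimulationConfig,
) -> list[ReadLibrary]:
    """IP + input libraries for every condition and replicate.

    Input fragments are sampled uniformly along transcripts with genes
    drawn proportional to expression; IP fragments are additionally
    weighted by methylated-site capture.  Gene-level gamma noise
    (negative-binomial gene counts) is drawn once per (condition,
    replicate) and shared by the IP and input libraries of that sample —
    both are aliquots of the same fragmented mRNA pool, so their
    expression fluctuations are common, not independent.  Reads are the
    5' ``read_length`` of each fragment.
    """
    config.validate()
    tids = sorted(models)
    lengths = np.array([models[t].length for t in tids])
    base_expr = gene_base_expression(config).reindex(tids).to_numpy()

    libraries: list[ReadLibrary] = []
    for ci, cond in enumerate(CONDITIONS):
        site_map = methylome_site_levels(methylome, cond)
        weights = [
            _ip_weights(models[t].length, site_map.get(t, ()), config) for t in tids
        ]
        mean_weight = np.array([w.mean() for w in weights])
        for rep in range(1, config.replicates + 1):
            expr = base_expr.copy()
            if config.dispersion > 0:
                shape = 1.0 / config.dispersion
                expr = expr * _rng(config, 4, ci, rep, 2).gamma(
                    shape, 1.0 / shape, len(tids)
                )
            for ai, assay in enumerate(("IP", "input")):
                rng = _rng(config, 4, ci, rep, ai)
                gene_p = expr * (mean_weight if assay == "IP" else 1.0)
                reads: dict[str, np.ndarray] = {}
                depth = config.depth_per_library
                if depth > 0 and gene_p.sum() > 0:
                    counts = rng.multinomial(depth, gene_p / gene_p.sum())
                    for g, n_g in enumerate(counts):
                        if n_g == 0:
                            continue
                        w = weights[g]
                        if assay == "IP" and w.max() > w.min():
                            starts = rng.choice(w.size, size=n_g, p=w / w.sum())
                        else:
                            starts = rng.integers(0, w.size, size=n_g)
                        starts = np.sort(starts)
                        ends = np.minimum(starts + config.read_length, lengths[g])
                        reads[tids[g]] = np.column_stack([starts, ends]).astype(
                            np.int64
                        )
                lib = ReadLibrary(
                    sample_id=f"{cond}_{assay}_rep{rep}",
                    condition=cond,
                    replicate=rep,
                    assay=assay,
                    reads=reads,
                    total_mapped=int(sum(len(v) for v in reads.values())),
                )
                libraries.append(lib)
    return libraries


# ---------------------------------------------------------------------------
# Expression matrix (microarray-style)
# ---------------------------------------------------------------------------

def simulate_expression_matrix(
    models: Mapping[str, TranscriptModel],
    methylome: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Log2 expression matrix (genes x samples) with planted upregulation.

    ``n_de_genes`` genes go up by ``de_fold`` in resistant samples,
    drawn preferentially from genes that lose methylation in the
    resistant condition (stabilisation of demethylated transcripts
    coupling methylation loss to expression gain).  Returns the matrix,
    the sample->group map, and a truth table of planted DE genes.
    """
    config.validate()
    rng = _rng(config, 5)
    tids = sorted(models)
    gene_ids = [models[t].gene_id for t in tids]
    base = _BASE_LOG2_EXPR + np.log2(gene_base_expression(config).reindex(tids).to_numpy())

    demeth_tids = set(demethylated_sites(methylome)["transcript_id"])
    demeth_genes = [models[t].gene_id for t in sorted(demeth_tids)]
    others = [g for g in gene_ids if g not in set(demeth_genes)]
    rng.shuffle(demeth_genes)
    rng.shuffle(others)
    planted = (demeth_genes + others)[: config.n_de_genes]

    k = config.array_replicates
    samples = [f"parental_{i + 1}" for i in range(k)] + [
        f"resistant_{i + 1}" for i in range(k)
    ]
    groups = {s: ("parental" if s.startswith("parental") else "resistant") for s in samples}
    mat = np.tile(base[:, None], (1, 2 * k))
    up = np.isin(gene_ids, planted)
    mat[up, k:] += np.log2(config.de_fold)
    if config.expression_noise_sd > 0:
        mat = mat + rng.normal(0.0, config.expression_noise_sd, mat.shape)
    expr = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_up": up,
            "demethylated": [g in set(demeth_genes) for g in gene_ids],
        }
    )
    return expr, groups, truth


# ---------------------------------------------------------------------------
# Decay courses
# ---------------------------------------------------------------------------

def simulate_decay_course(
    genes: Sequence[str],
    half_lives: Sequence[float],
    timepoints: Sequence[float],
    config: SimulationConfig,
) -> list[DecayCourse]:
    """CT-space actinomycin-D chase: target CT rises 1 cycle per halving.

    ``CT_target(t) = CT_target(0) + t / half_life``; the reference gene
    is perfectly stable.  Infinite half-life gives a flat course.
    Gaussian CT noise of sd ``config.ct_noise_sd`` is added per well;
    each timepoint is measured in ``config.qpcr_replicates`` technical
    wells (downstream analysis averages them in CT space).
    """
    config.validate()
    rng = _rng(config, 6)
    t = np.asarray(timepoints, dtype=float)
    n_rep = max(1, config.qpcr_replicates)
    courses = []
    for gene, hl in zip(genes, half_lives):
        if not np.isinf(hl) and hl <= 0:
            raise ValueError(f"{gene}: half-life must be positive or infinite")
        ct0 = 22.0
        ct_t = ct0 + (np.zeros_like(t) if np.isinf(hl) else t / hl)
        ct_r = np.full_like(t, 16.0)
        if config.ct_noise_sd > 0:
            ct_t = ct_t[:, None] + rng.normal(0.0, config.ct_noise_sd, (t.size, n_rep))
            ct_r = ct_r[:, None] + rng.normal(0.0, config.ct_noise_sd, (t.size, n_rep))
        courses.append(
            DecayCourse(gene_id=gene, timepoints=t, ct_target=ct_t, ct_reference=ct_r)
        )
    return courses


# ---------------------------------------------------------------------------
# Full dataset + on-disk layout
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate all artifacts of one synthetic study."""
    models = simulate_transcriptome(config)
    methylome = simulate_methylome(models, config)
    libraries = simulate_libraries(models, methylome, config)
    expr, groups, truth = simulate_expression_matrix(models, methylome, config)
    genes = [g for g, _ in DEFAULT_DECAY_GENES]
    half_lives = [h for _, h in DEFAULT_DECAY_GENES]
    courses = simulate_decay_course(
        genes, half_lives, DEFAULT_DECAY_TIMEPOINTS, config
    )
    decay_truth = pd.DataFrame({"gene_id": genes, "true_t_half": half_lives})
    return SimulatedDataset(
        config=config,
        models=models,
        methylome=methylome,
        libraries=libraries,
        expression=expr,
        expression_groups=groups,
        expression_truth=truth,
        decay_courses=courses,
        decay_truth=decay_truth,
    )


def write_simulation(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset to ``out_dir`` in the pipeline's exchange formats."""
    out = Path(out_dir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    paths["models"] = out / "models.gtf"
    mio.write_transcript_models(dataset.models, paths["models"])
    paths["fasta"] = out / "transcripts.fa"
    mio.write_fasta(
        {t: m.sequence for t, m in dataset.models.items() if m.sequence}, paths["fasta"]
    )
    paths["methylome"] = out / "methylome.tsv"
    mio.write_table(dataset.methylome, paths["methylome"])
    for lib in dataset.libraries:
        p = out / "reads" / f"{lib.sample_id}.bed"
        mio.write_read_library(lib, p)
        paths[f"reads/{lib.sample_id}"] = p
    paths["expression"] = out / "expression.tsv"
    mio.write_table(dataset.expression.reset_index(), paths["expression"])
    groups_df = pd.DataFrame(
        sorted(dataset.expression_groups.items()), columns=["sample", "group"]
    )
    paths["groups"] = out / "truth" / "groups.tsv"
    mio.write_table(groups_df, paths["groups"])
    paths["expression_truth"] = out / "truth" / "expression_truth.tsv"
    mio.write_table(dataset.expression_truth, paths["expression_truth"])
    paths["demethylated_sites"] = out / "truth" / "demethylated_sites.tsv"
    mio.write_table(demethylated_sites(dataset.methylome), paths["demethylated_sites"])
    if dataset.decay_courses:
        paths["decay_ct"] = out / "decay_ct.tsv"
        mio.write_table(decay_courses_to_table(dataset.decay_courses), paths["decay_ct"])
    if dataset.decay_truth is not None:
        paths["decay_truth"] = out / "truth" / "decay_truth.tsv"
        mio.write_table(dataset.decay_truth, paths["decay_truth"])
    config_df = pd.DataFrame(
        [(k, str(v)) for k, v in asdict(dataset.config).items()],
        columns=["parameter", "value"],
    )
    paths["config"] = out / "truth" / "sim_config.tsv"
    mio.write_table(config_df, paths["config"])
    return paths


def evaluate_peak_calls(
    peaks_by_group: Mapping[str, Sequence],
    methylome: pd.DataFrame,
    motif_length: int = len(_PLANTED_MOTIF),
) -> pd.DataFrame:
    """Recall/precision of called peaks against the planted methylome.

    A site methylated in a condition counts as recovered when any of
    that condition's peaks overlaps its motif span; a peak counts as a
    true positive when it overlaps any methylated site.  Returns one row
    per condition plus a pooled row.
    """
    rows = []
    tot_sites = tot_hit = tot_peaks = tot_tp = 0
    for cond, peaks in sorted(peaks_by_group.items()):
        sub = methylome[
            (methylome["condition"] == cond) & (methylome["methylation_level"] > 0)
        ]
        sites = {
            tid: grp["site_position"].to_numpy()
            for tid, grp in sub.groupby("transcript_id")
        }
        n_sites = int(len(sub))
        hit = 0
        for tid, positions in sites.items():
            tid_peaks = [p for p in peaks if p.transcript_id == tid]
            for pos in positions:
                if any(p.start < pos + motif_length and p.end > pos for p in tid_peaks):
                    hit += 1
        tp = 0
        for p in peaks:
            positions = sites.get(p.transcript_id)
            if positions is not None and (
                (positions < p.end) & (positions + motif_length > p.start)
            ).any():
                tp += 1
        rows.append(
            {
                "condition": cond,
                "n_sites": n_sites,
                "n_peaks": len(peaks),
                "recall": hit / n_sites if n_sites else float("nan"),
                "precision": tp / len(peaks) if peaks else float("nan"),
            }
        )
        tot_sites += n_sites
        tot_hit += hit
        tot_peaks += len(peaks)
        tot_tp += tp
    rows.append(
        {
            "condition": "pooled",
            "n_sites": tot_sites,
            "n_peaks": tot_peaks,
            "recall": tot_hit / tot_sites if tot_sites else float("nan"),
            "precision": tot_tp / tot_peaks if tot_peaks else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def decay_courses_to_table(courses: Sequence[DecayCourse]) -> pd.DataFrame:
    """Long-format CT table: gene_id, time_h, ct_target, ct_reference."""
    rows = []
    for c in courses:
        ct_t, ct_r = c.mean_ct()
        for t, a, b in zip(c.timepoints, ct_t, ct_r):
            rows.append((c.gene_id, t, a, b, c.reference_gene))
    return pd.DataFrame(
        rows, columns=["gene_id", "time_h", "ct_target", "ct_reference", "reference_gene"]
    )


def decay_courses_from_table(table: pd.DataFrame) -> list[DecayCourse]:
    """Inverse of :func:`decay_courses_to_table`."""
    courses = []
    for gene, grp in table.groupby("gene_id", sort=True):
        grp = grp.sort_values("time_h")
        courses.append(
            DecayCourse(
                gene_id=str(gene),
                timepoints=grp["time_h"].to_numpy(),
                ct_target=grp["ct_target"].to_numpy(),
                ct_reference=grp["ct_reference"].to_numpy(),
                reference_gene=str(grp["reference_gene"].iloc[0])
                if "reference_gene" in grp
                else "GAPDH",
            )
        )
    return courses
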