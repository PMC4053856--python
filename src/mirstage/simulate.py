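"""Synthetic staged small-RNA-seq data with planted expression programs.

The generator emulates a bulk reprogramming time course: a set of stage
groups (default MEF, Thy1-, SSEA1+, Oct4-GFP+, piPSC, iPSC, mES) sequenced
in two replicate libraries prepared with different kits, hence a systematic
per-miRNA batch offset between replicates. Counts are negative-binomial with
edgeR-style dispersion (var = mu + phi*mu^2). Co-expression structure comes
solely from shared stage programs: each miRNA belongs to exactly one program
whose per-stage log2 offsets (relative to the first stage) shift its mean.

Default programs encode the study's archetypes: an imprinted-cluster module
with an abrupt drop at the first transition followed by gradual recovery
(Dlk1-Dio3-like), a mesenchymal-to-epithelial-transition spike, a monotone
stem-cell ramp with a large late jump, a monotone decline, and a null
background. Together these produce the staged fold-change regime: many
small-magnitude changes at the first transition, few large ones at the last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CountMatrix

__all__ = [
    "ProgramSpec",
    "SimConfig",
    "PlantedTruth",
    "default_programs",
    "default_config",
    "expected_cpm",
    "generate_counts",
    "generate_isomir_reads",
    "REPROGRAMMING_STAGES",
]

REPROGRAMMING_STAGES = ("MEF", "Thy1-", "SSEA1+", "Oct4-GFP+", "piPSC", "iPSC", "mES")


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class ProgramSpec:
    """A planted co-expression program.

    stage_log2fc gives per-stage log2 offsets relative to the first stage
    (so its first entry must be 0); all member miRNAs share this trajectory.
    """

    name: str
    n_members: int
    stage_log2fc: tuple[float, ...]
    cluster_tag: str | None = None


def default_programs(stages=REPROGRAMMING_STAGES) -> list[ProgramSpec]:
    """The archetypal programs of the staged reprogramming regime (7 stages)."""
    if len(stages) != 7:
        raise ConfigError("default_programs assumes the 7 default stages")
    return [
        # abrupt down at the first transition, gradual recovery later
        ProgramSpec("imprinted_down_up", 60,
                    (0.0, -2.0, -1.6, -1.0, -1.8, -0.4, -0.2), cluster_tag="Dlk1-Dio3"),
        # transient MET spike at the SSEA1+ stage
        ProgramSpec("met_spike", 10, (0.0, 0.3, 4.0, 1.5, 1.0, 0.8, 0.8)),
        # monotone stem-cell ramp: small early steps, one large late jump
        ProgramSpec("stem_ramp", 15, (0.0, 0.4, 1.2, 7.2, 5.0, 7.0, 7.4)),
        # monotone decline of somatic miRNAs
        ProgramSpec("decline", 30, (0.0, -1.2, -2.2, -3.0, -2.6, -3.2, -3.4)),
        ProgramSpec("null", 185, (0.0,) * 7),
    ]


@dataclass
class SimConfig:
    """Generator settings; defaults are the emulated study conditions.

    Library sizes default to 15e6 (replicate 1) and 25e6 (replicate 2),
    matching the order of magnitude of the two kits' read yields; scale
    them down for fast tests.
    """

    n_mirnas: int | None = None
    stages: tuple[str, ...] = REPROGRAMMING_STAGES
    n_replicates: int = 2
    lib_sizes: tuple[float, ...] = (15e6, 25e6)
    dispersion: float = 0.1
    batch_logfc_sd: float = 0.3
    programs: list[ProgramSpec] = field(default_factory=default_programs)
    baseline_log2cpm_range: tuple[float, float] = (2.0, 9.0)
    seed: int = 0
    deterministic: bool = False

    def __post_init__(self) -> None:
        if not self.stages or len(set(self.stages)) != len(self.stages):
            raise ConfigError("stages: must be non-empty and unique")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates: must be >= 1")
        if len(self.lib_sizes) != self.n_replicates:
            raise ConfigError("lib_sizes: need one expected total per replicate")
        if any(l <= 0 for l in self.lib_sizes):
            raise ConfigError("lib_sizes: must all be > 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion: must be >= 0")
        if self.batch_logfc_sd < 0:
            raise ConfigError("batch_logfc_sd: must be >= 0")
        for p in self.programs:
            if len(p.stage_log2fc) != len(self.stages):
                raise ConfigError(
                    f"programs: {p.name} stage_log2fc length {len(p.stage_log2fc)} "
                    f"!= number of stages {len(self.stages)}")
            if p.stage_log2fc[0] != 0.0:
                raise ConfigError(f"programs: {p.name} stage_log2fc[0] must be 0")
            if p.n_members < 0:
                raise ConfigError(f"programs: {p.name} n_members must be >= 0")
        total = sum(p.n_members for p in self.programs)
        if self.n_mirnas is None:
            self.n_mirnas = total
        elif self.n_mirnas != total:
            raise ConfigError(
                f"n_mirnas: {self.n_mirnas} != sum of program sizes {total}")
        lo, hi = self.baseline_log2cpm_range
        if hi < lo:
            raise ConfigError("baseline_log2cpm_range: must be (low, high)")


def default_config(**overrides) -> SimConfig:
    return SimConfig(**overrides)


@dataclass
class PlantedTruth:
    """Ground truth for recovery tests.

    program_of : miRNA id -> program name (every miRNA has exactly one).
    true_log2fc : miRNA x transition matrix of planted consecutive-stage
        log2 fold changes.
    isomir_shift_of : miRNA id -> (offset, fraction, stage group) for planted
        5' start-site switches.
    """

    program_of: pd.Series
    true_log2fc: pd.DataFrame
    isomir_shift_of: dict = field(default_factory=dict)


def _layout(config: SimConfig):
    """Sample ids/metadata and the per-miRNA program assignment, deterministically."""
    sample_ids, stages, reps = [], [], []
    for r in range(1, config.n_replicates + 1):
        for st in config.stages:
            sample_ids.append(f"{st}_r{r}")
            stages.append(st)
            reps.append(f"rep{r}")
    samples = pd.DataFrame({"stage": stages, "replicate": reps},
                           index=pd.Index(sample_ids, name="sample_id"))
    mirna_ids, prog_of = [], []
    for p in config.programs:
        for i in range(p.n_members):
            mirna_ids.append(f"{p.name}-mir-{i + 1:03d}")
            prog_of.append(p.name)
    program_of = pd.Series(prog_of, index=pd.Index(mirna_ids, name="mirna_id"),
                           name="program")
    return samples, program_of


def expected_cpm(config: SimConfig, baseline_log2cpm: np.ndarray,
                 batch_log2: np.ndarray) -> pd.DataFrame:
    """Expected cpm per miRNA and sample implied by the generative model.

    cpm_{g,s} = 2^(baseline_g + program_log2fc_{g, stage(s)} + batch_g * [rep(s) != rep1]).
    """
    samples, program_of = _layout(config)
    prog_fc = {p.name: np.asarray(p.stage_log2fc) for p in config.programs}
    stage_idx = {st: j for j, st in enumerate(config.stages)}
    out = np.empty((len(program_of), len(samples)))
    for si, (sid, row) in enumerate(samples.iterrows()):
        j = stage_idx[row["stage"]]
        fc = np.array([prog_fc[p][j] for p in program_of])
        b = batch_log2 if row["replicate"] != "rep1" else 0.0
        out[:, si] = 2.0 ** (baseline_log2cpm + fc + b)
    return pd.DataFrame(out, index=program_of.index, columns=samples.index)


def generate_counts(config: SimConfig):
    """Draw a staged count matrix; returns (CountMatrix, annotation, PlantedTruth).

    Counts are NB(mean = lib_size * cpm / 1e6, var = mu + phi*mu^2), Poisson at
    phi = 0, or rounded means in deterministic mode. The annotation table is
    BED-like with one synthetic locus per miRNA; members of programs with a
    cluster_tag share that genomic-cluster label.
    """
    rng = np.random.default_rng(config.seed)
    samples, program_of = _layout(config)
    n_g = len(program_of)
    lo, hi = config.baseline_log2cpm_range
    baseline = rng.uniform(lo, hi, size=n_g)
    batch = (rng.normal(0.0, config.batch_logfc_sd, size=n_g)
             if config.batch_logfc_sd > 0 else np.zeros(n_g))
    ecpm = expected_cpm(config, baseline, batch)
    lib_of_rep = {f"rep{r + 1}": config.lib_sizes[r] for r in range(config.n_replicates)}
    libs = samples["replicate"].map(lib_of_rep).to_numpy(dtype=float)
    mu = ecpm.to_numpy() * libs[None, :] / 1e6
    if config.deterministic:
        counts = np.round(mu).astype(np.int64)
    elif config.dispersion == 0:
        counts = rng.poisson(mu).astype(np.int64)
    else:
        r = 1.0 / config.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p).astype(np.int64)
    cm = CountMatrix(pd.DataFrame(counts, index=program_of.index, columns=samples.index),
                     samples)

    # BED-like annotation: chrom, start, end, name, cluster_tag, strand
    tag_of = {p.name: (p.cluster_tag or ".") for p in config.programs}
    ann = pd.DataFrame({
        "chrom": ["chrS"] * n_g,
        "start": np.arange(n_g) * 200 + 100,
        "end": np.arange(n_g) * 200 + 122,
        "name": program_of.index,
        "cluster_tag": [tag_of[p] for p in program_of],
        "strand": ["+" if i % 2 == 0 else "-" for i in range(n_g)],
    })

    prog_fc = {p.name: np.asarray(p.stage_log2fc) for p in config.programs}
    transitions = [f"{a}->{b}" for a, b in zip(config.stages[:-1], config.stages[1:])]
    tfc = np.array([np.diff(prog_fc[p]) for p in program_of])
    truth = PlantedTruth(
        program_of=program_of,
        true_log2fc=pd.DataFrame(tfc, index=program_of.index, columns=transitions),
    )
    return cm, ann, truth


# background 5' start-site heterogeneity of an unswitched miRNA
_BACKGROUND_OFFSETS = {0: 0.88, -1: 0.05, 1: 0.05, -2: 0.01, 2: 0.01}


def _allocate(dist: dict[int, float], total: int, rng, deterministic: bool):
    offs = sorted(dist)
    probs = np.array([dist[o] for o in offs], dtype=float)
    probs = probs / probs.sum()
    if deterministic:
        # largest-remainder rounding so worked examples are exact
        raw = probs * total
        base = np.floor(raw).astype(int)
        rem = total - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
        cts = base
    else:
        cts = rng.multinomial(total, probs)
    return {o: int(c) for o, c in zip(offs, cts) if c > 0}


def generate_isomir_reads(config: SimConfig, switching_spec=(),
                          n_reads: int = 1000, deterministic: bool | None = None):
    """Per-(miRNA, sample) 5' offset read tables with planted switches.

    switching_spec is a list of (mirna_id, offset, fraction, stage_group); in
    the named stage's samples that miRNA has expected shifted-read fraction
    ``fraction`` at ``offset`` and the remainder at the canonical start.
    Elsewhere, and for unflagged miRNAs, reads follow a background
    distribution concentrating >=95% of reads at offsets {0, -1, +1}.
    """
    if deterministic is None:
        deterministic = config.deterministic
    rng = np.random.default_rng(config.seed + 1)
    samples, program_of = _layout(config)
    known = set(program_of.index)
    spec_of: dict[str, list] = {}
    for mirna, off, frac, group in switching_spec:
        if mirna not in known:
            raise KeyError(f"unknown miRNA in switching spec: {mirna}")
        if group not in set(config.stages):
            raise KeyError(f"unknown sample group in switching spec: {group}")
        if not 0.0 <= frac <= 1.0:
            raise ConfigError(f"switching fraction for {mirna} not in [0,1]: {frac}")
        if off != int(off):
            raise ConfigError(f"offset for {mirna} must be an integer: {off}")
        spec_of.setdefault(mirna, []).append((int(off), float(frac), group))

    records = []
    for mirna in program_of.index:
        for sid, row in samples.iterrows():
            dist = dict(_BACKGROUND_OFFSETS)
            for off, frac, group in spec_of.get(mirna, []):
                if row["stage"] == group:
                    dist = {0: 1.0 - frac, off: frac} if frac < 1.0 else {off: 1.0}
            for off, c in _allocate(dist, n_reads, rng, deterministic).items():
                records.append((mirna, sid, off, c))
    table = pd.DataFrame(records, columns=["mirna_id", "sample_id", "offset", "count"])
    truth = PlantedTruth(
        program_of=program_of,
        true_log2fc=pd.DataFrame(index=program_of.index),
        isomir_shift_of={m: specs for m, specs in spec_of.items()},
    )
    return table, truth


def write_annotation(ann: pd.DataFrame, path) -> None:
    """Write the BED-like annotation table (0-based half-open) as TSV."""
    ann.to_csv(path, sep="\t", index=False, header=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "cluster_tag", "strand"])
    return ann
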