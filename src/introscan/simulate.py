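"""Seeded synthetic genotype cohorts with planted ground truth.

The generator emulates the statistical structure of a multi-species SNP
cohort without a full coalescent: ancestral allele frequencies are drawn
from a symmetric Beta, each population's frequency from the
Balding-Nichols model around the ancestral value with its own drift
parameter F, and diploid genotypes are binomial draws. An outgroup is
emitted as a fixed-allele pseudo-population for polarization (with a
small probability d_out that the outgroup carries the derived allele,
emulating polarization error).

Two kinds of signal are planted on top, with truth recorded:

* donor -> recipient introgression tracts: within each tract every
  recipient haplotype is, independently with probability alpha, an
  ancestry draw from the donor population for the whole tract;
* selective sweeps: within listed windows the target cohort's allele
  frequencies are pushed toward a shared fixation side so per-site
  heterozygosity drops by the configured factor.

Randomness is consumed in a documented order from seed-sequence child
streams (base cohort, then one stream per planted event), so output is
bit-reproducible for a given config and planting is local: genotypes
outside a planted interval are identical to an unplanted run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable, PopulationMap, write_vcf

__all__ = ["PopulationSpec", "IntrogressionEvent", "SweepEvent", "SimConfig",
           "SimulatedCohort", "simulate_cohort", "plant_introgression",
           "plant_sweep", "demo_config", "null_config", "write_outputs"]


@dataclass
class PopulationSpec:
    label: str
    n_diploids: int
    drift_f: float  # Balding-Nichols F in [0, 1)

    def __post_init__(self) -> None:
        if self.n_diploids <= 0:
            raise ValueError(f"{self.label}: n_diploids must be positive")
        if not 0 <= self.drift_f < 1:
            raise ValueError(f"{self.label}: drift F must be in [0, 1)")


@dataclass
class IntrogressionEvent:
    donor: str
    recipient: str
    alpha: float = 0.5
    n_tracts: int = 20
    mean_tract_length: int = 500_000

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_tracts < 0 or self.mean_tract_length <= 0:
            raise ValueError("invalid tract configuration")


@dataclass
class SweepEvent:
    cohort: list[str]
    windows: list[tuple[str, int, int]]
    reduction: float = 10.0

    def __post_init__(self) -> None:
        if self.reduction <= 1:
            raise ValueError("diversity reduction factor must exceed 1")


@dataclass
class SimConfig:
    seed: int
    contigs: dict[str, int]
    site_density: float = 0.001  # expected SNPs per bp
    populations: list[PopulationSpec] = field(default_factory=list)
    outgroup_label: str = "goat"
    n_outgroup: int = 1
    d_out: float = 0.05
    beta_shape: float = 0.8  # ancestral-frequency Beta(a, a)
    introgression: list[IntrogressionEvent] = field(default_factory=list)
    sweeps: list[SweepEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.contigs or any(v <= 0 for v in self.contigs.values()):
            raise ValueError("contigs must have positive lengths")
        if not 0 < self.site_density <= 1:
            raise ValueError("site_density must be in (0, 1]")
        if not 0 <= self.d_out <= 1:
            raise ValueError("d_out must be in [0, 1]")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        for ev in self.introgression:
            if ev.donor not in labels or ev.recipient not in labels:
                raise ValueError("introgression event names unknown population")
        for sw in self.sweeps:
            if any(p not in labels for p in sw.cohort):
                raise ValueError("sweep cohort names unknown population")
            for c, s, e in sw.windows:
                if c not in self.contigs or not 0 <= s < e <= self.contigs[c]:
                    raise ValueError(f"sweep window outside contig: {(c, s, e)}")


@dataclass
class SimulatedCohort:
    """A simulated genotype cohort with its latent state and truth sets."""

    config: SimConfig
    gt: GenotypeTable
    popmap: PopulationMap
    pop_freq: np.ndarray          # (n_pops, n_sites) latent frequencies
    ancestral_freq: np.ndarray    # (n_sites,)
    truth_tracts: pd.DataFrame    # chrom,start,end,donor,recipient,alpha,realized_alpha
    truth_sweeps: pd.DataFrame    # chrom,start,end,reduction

    @property
    def pop_labels(self) -> list[str]:
        return [p.label for p in self.config.populations]

    def _pop_cols(self, label: str) -> list[int]:
        return [self.gt.samples.index(s)
                for s in self.popmap.samples_of(label)]


def _draw_positions(rng: np.random.Generator, length: int,
                    density: float) -> np.ndarray:
    n = int(round(length * density))
    return np.unique(rng.integers(0, length, size=n))


def _balding_nichols(rng: np.random.Generator, p_anc: np.ndarray,
                     f: float) -> np.ndarray:
    if f == 0:
        return p_anc.copy()
    c = (1.0 - f) / f
    return rng.beta(np.maximum(p_anc * c, 1e-12),
                    np.maximum((1.0 - p_anc) * c, 1e-12))


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate the full cohort: base drift structure, then every planted
    introgression and sweep event, in the order they appear in the config."""
    ss = np.random.SeedSequence(config.seed)
    n_events = len(config.introgression) + len(config.sweeps)
    streams = [np.random.default_rng(c) for c in ss.spawn(1 + n_events)]
    cohort = _base_cohort(config, streams[0])
    k = 1
    for ev in config.introgression:
        cohort = plant_introgression(cohort, ev, streams[k])
        k += 1
    for sw in config.sweeps:
        cohort = plant_sweep(cohort, sw, streams[k])
        k += 1
    return cohort


def _base_cohort(config: SimConfig, rng: np.random.Generator) -> SimulatedCohort:
    chroms, poss = [], []
    for c, length in config.contigs.items():
        p = _draw_positions(rng, length, config.site_density)
        chroms.append(np.full(p.size, c, dtype=object))
        poss.append(p)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    s = pos.size
    a = config.beta_shape
    p_anc = rng.beta(a, a, size=s)
    pops = config.populations
    pop_freq = np.empty((len(pops), s))
    geno_cols = []
    samples = []
    assignments = {}
    for k, spec in enumerate(pops):
        pop_freq[k] = _balding_nichols(rng, p_anc, spec.drift_f)
        g = rng.binomial(2, pop_freq[k][:, None],
                         size=(s, spec.n_diploids)).astype(np.int8)
        geno_cols.append(g)
        for j in range(spec.n_diploids):
            name = f"{spec.label}_{j + 1}"
            samples.append(name)
            assignments[name] = spec.label
    # outgroup: fixed hom-ref (ancestral) except at d_out sites, where the
    # outgroup is fixed for the allele that is derived in the ingroup
    og_derived = rng.random(s) < config.d_out
    og_code = np.where(og_derived, 2, 0).astype(np.int8)
    og = np.repeat(og_code[:, None], config.n_outgroup, axis=1)
    for j in range(config.n_outgroup):
        name = f"{config.outgroup_label}_{j + 1}"
        samples.append(name)
        assignments[name] = config.outgroup_label
    genotypes = np.hstack(geno_cols + [og])
    ref = np.full(s, "A", dtype=object)
    alt = np.full(s, "C", dtype=object)
    gt = GenotypeTable(chrom, pos, ref, alt, genotypes, samples)
    pm = PopulationMap(assignments, outgroup=config.outgroup_label)
    empty_tracts = pd.DataFrame(columns=["chrom", "start", "end", "donor",
                                         "recipient", "alpha",
                                         "realized_alpha"])
    empty_sweeps = pd.DataFrame(columns=["chrom", "start", "end", "reduction"])
    return SimulatedCohort(config, gt, pm, pop_freq, p_anc,
                           empty_tracts, empty_sweeps)


def _draw_tracts(rng: np.random.Generator, contigs: dict[str, int],
                 n_tracts: int, mean_length: int,
                 max_tries: int = 10_000) -> list[tuple[str, int, int]]:
    """Non-overlapping tracts with exponential lengths (truncated at contig
    ends), contigs chosen proportional to length, placed by rejection."""
    names = list(contigs)
    lengths = np.array([contigs[c] for c in names], dtype=np.float64)
    if n_tracts * mean_length > 0.5 * lengths.sum():
        raise ValueError("requested tract mass exceeds half the genome; "
                         "rejection placement would not terminate reliably")
    placed: list[tuple[str, int, int]] = []
    tries = 0
    while len(placed) < n_tracts:
        if tries > max_tries:
            raise RuntimeError("could not place non-overlapping tracts")
        tries += 1
        ci = rng.choice(len(names), p=lengths / lengths.sum())
        c = names[ci]
        tl = max(1, int(rng.exponential(mean_length)))
        start = int(rng.integers(0, contigs[c]))
        end = min(start + tl, contigs[c])
        if any(cc == c and start < ee and end > ss for cc, ss, ee in placed):
            continue
        placed.append((c, start, end))
    placed.sort(key=lambda t: (t[0], t[1]))
    return placed


def plant_introgression(cohort: SimulatedCohort, event: IntrogressionEvent,
                        rng: np.random.Generator) -> SimulatedCohort:
    """Plant one donor -> recipient introgression event.

    Draws the event's tracts, then inside each tract assigns every
    recipient haplotype donor ancestry independently with probability
    alpha; donor haplotypes are Bernoulli draws from the donor's latent
    frequency, the rest are redrawn from the recipient's (statistically
    unchanged). Genotypes outside the tracts are untouched. Records the
    realized replaced-haplotype fraction per tract.
    """
    cfg = cohort.config
    labels = cohort.pop_labels
    kd, kr = labels.index(event.donor), labels.index(event.recipient)
    cols = cohort._pop_cols(event.recipient)
    tracts = _draw_tracts(rng, cfg.contigs, event.n_tracts,
                          event.mean_tract_length)
    geno = cohort.gt.genotypes.copy()
    rows = []
    for c, s, e in tracts:
        sel = np.flatnonzero((cohort.gt.chrom == c) & (cohort.gt.pos >= s)
                             & (cohort.gt.pos < e))
        is_donor = rng.random((len(cols), 2)) < event.alpha
        realized = float(is_donor.mean()) if event.alpha > 0 else 0.0
        if sel.size:
            p_d = cohort.pop_freq[kd, sel]
            p_r = cohort.pop_freq[kr, sel]
            # (sites, samples, 2) haplotype draws with per-haplotype ancestry
            p_hap = np.where(is_donor[None, :, :], p_d[:, None, None],
                             p_r[:, None, None])
            haps = rng.random((sel.size, len(cols), 2)) < p_hap
            geno[np.ix_(sel, cols)] = haps.sum(axis=2).astype(np.int8)
        rows.append((c, s, e, event.donor, event.recipient, event.alpha,
                     realized))
    gt = GenotypeTable(cohort.gt.chrom, cohort.gt.pos, cohort.gt.ref,
                       cohort.gt.alt, geno, list(cohort.gt.samples))
    new = pd.DataFrame(rows, columns=["chrom", "start", "end", "donor",
                                      "recipient", "alpha", "realized_alpha"])
    truth = (new if cohort.truth_tracts.empty else
             pd.concat([cohort.truth_tracts, new], ignore_index=True)
             ) if rows else cohort.truth_tracts
    return SimulatedCohort(cfg, gt, cohort.popmap, cohort.pop_freq,
                           cohort.ancestral_freq, truth, cohort.truth_sweeps)


def _sweep_freq(p: np.ndarray, reduction: float, push_up: np.ndarray) -> np.ndarray:
    """Frequency with heterozygosity p(1-p) reduced by ``reduction``,
    moved toward 1 where push_up else toward 0."""
    h = p * (1.0 - p) / reduction
    root = np.sqrt(np.maximum(0.25 - h, 0.0))
    return np.where(push_up, 0.5 + root, 0.5 - root)


def plant_sweep(cohort: SimulatedCohort, event: SweepEvent,
                rng: np.random.Generator) -> SimulatedCohort:
    """Plant low-diversity sweep windows in the target cohort.

    Inside each window, every cohort population's latent frequency is
    replaced by one with per-site heterozygosity divided by the event's
    reduction factor, pushed toward a fixation side shared across the
    cohort (the side favoured by the cohort-pooled frequency, so pooled
    diversity drops too); cohort genotypes there are redrawn. Other
    populations and all other windows are untouched bit-for-bit.
    """
    cfg = cohort.config
    labels = cohort.pop_labels
    ks = [labels.index(p) for p in event.cohort]
    sizes = np.array([cfg.populations[k].n_diploids for k in ks], float)
    geno = cohort.gt.genotypes.copy()
    pop_freq = cohort.pop_freq.copy()
    rows = []
    for c, s, e in event.windows:
        sel = np.flatnonzero((cohort.gt.chrom == c) & (cohort.gt.pos >= s)
                             & (cohort.gt.pos < e))
        if sel.size:
            pooled = (pop_freq[np.ix_(ks, sel)]
                      * sizes[:, None]).sum(axis=0) / sizes.sum()
            push_up = pooled >= 0.5
            for k in ks:
                p_new = _sweep_freq(pop_freq[k, sel], event.reduction, push_up)
                pop_freq[k, sel] = p_new
                cols = cohort._pop_cols(labels[k])
                geno[np.ix_(sel, cols)] = rng.binomial(
                    2, p_new[:, None], size=(sel.size, len(cols))
                ).astype(np.int8)
        rows.append((c, s, e, event.reduction))
    gt = GenotypeTable(cohort.gt.chrom, cohort.gt.pos, cohort.gt.ref,
                       cohort.gt.alt, geno, list(cohort.gt.samples))
    new = pd.DataFrame(rows, columns=["chrom", "start", "end", "reduction"])
    truth = (new if cohort.truth_sweeps.empty else
             pd.concat([cohort.truth_sweeps, new], ignore_index=True))
    return SimulatedCohort(cfg, gt, cohort.popmap, pop_freq,
                           cohort.ancestral_freq, cohort.truth_tracts, truth)


def demo_config(seed: int = 0) -> SimConfig:
    """The default demo cohort: eight populations with the study-like
    sample sizes and drift levels (a strongly drifted, low-diversity
    snow-sheep-like donor; bottlenecked domestic breeds), one donor ->
    recipient introgression event of 20 tracts with mean 500 kb at
    alpha = 0.5 (~3.7% of the 270-Mb genome), and ten 100-kb sweep
    windows with a 10x diversity reduction in the domestic cohort."""
    contigs = {"chr1": 90_000_000, "chr2": 90_000_000, "chr3": 90_000_000}
    sweep_windows = [("chr1", 5_000_000 + 8_000_000 * i,
                      5_100_000 + 8_000_000 * i) for i in range(5)]
    sweep_windows += [("chr2", 7_000_000 + 9_000_000 * i,
                       7_100_000 + 9_000_000 * i) for i in range(5)]
    return SimConfig(
        seed=seed,
        contigs=contigs,
        # ~3 raw SNPs/kb so ~2.5/kb survive the MAF filter, the density of
        # the emulated cohort's high-quality SNP set
        site_density=0.003,
        populations=[
            # drift F per population chosen as 1 - pi_pop/pi_ancestral to
            # reproduce the relative diversities of the emulated cohort
            # (bottlenecked domestic breeds ~0.0032, Asiatic mouflon ~0.0044,
            # snow sheep ~0.00075 per bp)
            PopulationSpec("OUE", 3, 0.30),
            PopulationSpec("SHA", 5, 0.25),
            PopulationSpec("GMA", 10, 0.25),
            PopulationSpec("AMUF", 16, 0.02),
            PopulationSpec("EMUF", 3, 0.35),
            PopulationSpec("URIS", 7, 0.08),
            PopulationSpec("ARGS", 8, 0.25),
            PopulationSpec("SNWS", 8, 0.80),
        ],
        introgression=[IntrogressionEvent("SNWS", "AMUF", alpha=0.5,
                                          n_tracts=20,
                                          mean_tract_length=500_000)],
        sweeps=[SweepEvent(["OUE", "SHA", "GMA"], sweep_windows,
                           reduction=10.0)],
    )


def null_config(seed: int = 0) -> SimConfig:
    """No-gene-flow calibration cohort: four populations of 10 diploids,
    ~50k SNPs on one 50-Mb contig, moderate drift, nothing planted."""
    return SimConfig(
        seed=seed,
        contigs={"chr1": 50_000_000},
        site_density=0.001,
        populations=[PopulationSpec(f"P{i + 1}", 10, 0.1) for i in range(4)],
    )


def write_outputs(cohort: SimulatedCohort, out_dir: str) -> None:
    """Write VCF, popmap TSV, truth BEDs and a resolved-config echo."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    write_vcf(cohort.gt, os.path.join(out_dir, "cohort.vcf"),
              cohort.config.contigs)
    with open(os.path.join(out_dir, "popmap.tsv"), "w") as fh:
        fh.write("#sample\tpopulation\n")
        for s_, p_ in cohort.popmap.assignments.items():
            fh.write(f"{s_}\t{p_}\n")
    cohort.truth_tracts.to_csv(os.path.join(out_dir, "truth_tracts.bed"),
                               sep="\t", header=False, index=False)
    cohort.truth_sweeps.to_csv(os.path.join(out_dir, "truth_sweeps.bed"),
                               sep="\t", header=False, index=False)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(asdict(cohort.config), fh, indent=2, default=str)
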