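"""Synthetic data with the statistical structure the pipeline assumes.

Three levels of simulation, all seeded and deterministic:

* conversion tables drawn directly from the two-component binomial
  mixture under per-gene first-order kinetics with growth dilution
  (:func:`simulate_tables`),
* full reads from TTS windows of a (toy) host genome, with polyA tails,
  UMIs, planted T->C conversions and a cross-species spike-in fraction
  (:func:`simulate_reads`),
* perturbation time courses solved piecewise-analytically from
  dR/dt = pi - (delta + gamma) R with a degradation shutdown at t = 0
  and a delayed transcription adaptation (:func:`simulate_timecourse`).

The named scenario presets mirror an acute depletion series along the
5'-3' degradation pathway: the further downstream the depleted factor,
the stronger the degradation shutdown and the later the onset of the
transcriptional adaptation. The labeling model covers only molecules
made during the final 4tU pulse before each sample, as in a
pulse-at-harvest time-course design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomekit import ReferenceSet, revcomp
from .kinetics import pr_expected
from .mixturemodel import ConversionTable
from .dynamics import Trajectory
from .readkit import TtsWindow

__all__ = [
    "GeneKinetics",
    "SimConfig",
    "PerturbationScenario",
    "SimRead",
    "default_genes",
    "make_test_references",
    "simulate_tables",
    "simulate_reads",
    "simulate_timecourse",
    "scenario_library",
    "scenario_from_file",
    "write_fastq",
]

READ_LENGTH = 45
MEDIAN_HALF_LIFE = 8.2  # min, exponential-growth yeast transcriptome scale


@dataclass(frozen=True)
class GeneKinetics:
    """Ground-truth production and degradation rates for one gene."""

    gene_id: str
    pi: float
    delta: float


@dataclass
class SimConfig:
    """Study conditions for the generative model.

    Defaults are the conditions the pipeline targets: a ~9-minute 4tU
    pulse with a ~1-minute conversion lag, background conversion rate
    1e-3 and incorporation rate 0.05 per genomic T, growth at a 90-minute
    doubling time, and per-read genomic-T counts X ~ Binomial(45, 0.3)
    (a 45-nt read over ~30% T sequence). ``x_value`` switches to a fixed
    X for analytic tests. The seed is mandatory.
    """

    genes: list[GeneKinetics]
    seed: int
    gamma: float = math.log(2) / 90.0
    epsilon: float = 1e-3
    xi: float = 0.05
    t0: float = 1.0
    t_label: float = 9.0
    reads_per_gene: int = 2000
    x_n: int = READ_LENGTH
    x_p: float = 0.3
    x_value: int | None = None
    spike_fraction: float = 0.03
    dup_factor: float = 1.3
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        if not (0 <= self.epsilon < self.xi <= 1):
            raise ValueError("need 0 <= epsilon < xi <= 1")
        for v in (self.gamma, self.t0, self.t_label):
            if v < 0:
                raise ValueError("rates and times must be >= 0")
        for g in self.genes:
            if g.pi < 0 or g.delta < 0:
                raise ValueError(f"{g.gene_id}: rates must be >= 0")

    def true_pr(self, gene: GeneKinetics) -> float:
        return pr_expected(self.t_label, gene.delta, self.gamma, self.t0)

    def draw_x(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.x_value is not None:
            return np.full(size, self.x_value, dtype=np.int64)
        return rng.binomial(self.x_n, self.x_p, size=size)


def default_genes(
    n: int,
    rng: np.random.Generator,
    median_half_life: float = MEDIAN_HALF_LIFE,
    sigma_delta: float = 0.5,
    sigma_pi: float = 1.0,
) -> list[GeneKinetics]:
    """Log-normal (pi, delta) cohort centered on a fast-turnover median.

    delta is log-normal with median ln(2)/``median_half_life`` and the
    given log-scale spread; pi is an independent log-normal in arbitrary
    units. Drawn rates are truncated to the labeling dynamic range
    (half-life 1-180 min) so the cohort is informative for recovery
    studies.
    """
    mu = math.log(math.log(2) / median_half_life)
    deltas = np.exp(rng.normal(mu, sigma_delta, size=n))
    deltas = np.clip(deltas, math.log(2) / 180.0, math.log(2) / 1.0)
    pis = np.exp(rng.normal(0.0, sigma_pi, size=n))
    return [
        GeneKinetics(f"gene{i:04d}", float(p), float(d))
        for i, (p, d) in enumerate(zip(pis, deltas))
    ]


# ---------------------------------------------------------------------------
# conversion tables straight from the mixture


def simulate_tables(
    config: SimConfig,
) -> dict[str, tuple[ConversionTable, float, int]]:
    """Draw a conversion table per gene from the generative mixture.

    Each read picks recent/old membership with probability
    p_r = 1 - exp(-(t - t0)(delta + gamma)), a genomic-T count X from the
    configured distribution, and Y ~ Binomial(X, xi or epsilon). Returns
    gene id -> (table, true p_r, number of recent reads).
    """
    rng = np.random.default_rng(config.seed)
    out = {}
    for gene in config.genes:
        p_true = config.true_pr(gene)
        n = config.reads_per_gene
        recent = rng.random(n) < p_true
        xs = config.draw_x(rng, n)
        rates = np.where(recent, config.xi, config.epsilon)
        ys = rng.binomial(xs, rates)
        max_x = max(int(xs.max(initial=0)), 30)
        table = ConversionTable.from_pairs(xs, ys, scope=gene.gene_id, max_x=max_x)
        out[gene.gene_id] = (table, p_true, int(recent.sum()))
    return out


# ---------------------------------------------------------------------------
# read-level simulation


@dataclass
class SimRead:
    """One simulated read with its ground truth.

    ``anchor`` is the 5' position of the insert in plus-strand
    coordinates (start for '+', exclusive end for '-'); ``seq`` is the
    read in sequencing orientation, genomic insert followed by the polyA
    tail.
    """

    id: str
    seq: str
    contig: str
    strand: str
    anchor: int
    umi: str
    barcode: str = "ACCGTAA"
    gene: str | None = None
    is_spike: bool = False
    is_recent: bool = False


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, p_t: float = 0.3) -> str:
    probs = [0.3, 0.2, 0.2, p_t]
    probs = [x / sum(probs) for x in probs]
    return "".join(rng.choice(_BASES, size=n, p=probs))


def make_test_references(
    n_genes: int,
    rng: np.random.Generator,
    gene_spacing: int = 500,
    spike_length: int = 3000,
) -> tuple[ReferenceSet, ReferenceSet, list[TtsWindow]]:
    """A toy host genome with one TTS window per gene, plus a spike genome.

    Genes alternate strands along a single host contig; each window is
    the standard 300-upstream/100-downstream interval around its TTS.
    """
    margin = 400
    length = 2 * margin + n_genes * gene_spacing
    host = ReferenceSet({"chrS": _random_seq(rng, length)})
    spike = ReferenceSet({"chrK": _random_seq(rng, spike_length)})
    windows = []
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        tts = margin + i * gene_spacing + (300 if strand == "+" else 100)
        windows.append(TtsWindow.from_tts(f"gene{i:04d}", "chrS", strand, tts))
    return host, spike, windows


def _plant_read(
    rng: np.random.Generator,
    ref_seg: str,
    conv_rate: float,
    error_rate: float,
) -> str:
    """Apply T->C conversions and non-T sequencing errors to a segment."""
    chars = list(ref_seg)
    for i, b in enumerate(chars):
        if b == "T":
            if rng.random() < conv_rate:
                chars[i] = "C"
        elif b != "N" and rng.random() < error_rate:
            others = [c for c in "ACGT" if c != b]
            chars[i] = others[rng.integers(3)]
    return "".join(chars)


def simulate_reads(
    config: SimConfig,
    host: ReferenceSet,
    spike: ReferenceSet,
    windows: list[TtsWindow],
) -> tuple[list[SimRead], pd.DataFrame]:
    """Generate reads from TTS windows plus a spike-in read fraction.

    Molecules per gene are drawn at ``reads_per_gene / dup_factor`` and
    re-emitted with shared UMI and position to reach the configured
    duplication level. Spike reads are uniform over the spike genome
    (both strands) and carry only background conversions. Returns the
    reads and a per-gene truth table (pi, delta, true p_r, read and
    recent-molecule counts).
    """
    rng = np.random.default_rng(config.seed)
    window_by_gene = {w.transcript_id: w for w in windows}
    reads: list[SimRead] = []
    truth_rows = []
    read_no = 0
    for gene in config.genes:
        w = window_by_gene.get(gene.gene_id)
        if w is None:
            raise KeyError(f"gene {gene.gene_id} has no TTS window")
        contig_seq = host.contigs[w.contig]
        p_true = config.true_pr(gene)
        n_reads = config.reads_per_gene
        n_mol = max(1, int(round(n_reads / config.dup_factor)))
        molecules = []
        for _ in range(n_mol):
            recent = bool(rng.random() < p_true)
            start = int(rng.integers(w.start, w.end - READ_LENGTH + 1))
            plus_seg = contig_seq[start : start + READ_LENGTH]
            seg = plus_seg if w.strand == "+" else revcomp(plus_seg)
            seq = _plant_read(rng, seg, config.xi if recent else config.epsilon,
                              config.error_rate)
            anchor = start if w.strand == "+" else start + READ_LENGTH
            umi = "".join(rng.choice(_BASES, size=8))
            molecules.append((seq, anchor, umi, recent))
        emit = list(range(n_mol))
        emit += [int(i) for i in rng.integers(0, n_mol, size=n_reads - n_mol)]
        n_recent = 0
        for mi in emit:
            seq, anchor, umi, recent = molecules[mi]
            tail = "A" * int(rng.integers(8, 21))
            reads.append(
                SimRead(
                    id=f"r{read_no:07d}",
                    seq=seq + tail,
                    contig=w.contig,
                    strand=w.strand,
                    anchor=anchor,
                    umi=umi,
                    gene=gene.gene_id,
                    is_recent=recent,
                )
            )
            read_no += 1
        n_recent = sum(1 for _, _, _, r in molecules if r)
        truth_rows.append(
            (gene.gene_id, gene.pi, gene.delta, p_true, len(emit), n_mol, n_recent)
        )
    n_host = len(reads)
    f = config.spike_fraction
    n_spike = int(round(n_host * f / (1.0 - f))) if f > 0 else 0
    spike_names = list(spike.contigs)
    for _ in range(n_spike):
        name = spike_names[int(rng.integers(len(spike_names)))]
        seq_full = spike.contigs[name]
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, len(seq_full) - READ_LENGTH + 1))
        plus_seg = seq_full[start : start + READ_LENGTH]
        seg = plus_seg if strand == "+" else revcomp(plus_seg)
        seq = _plant_read(rng, seg, config.epsilon, config.error_rate)
        anchor = start if strand == "+" else start + READ_LENGTH
        reads.append(
            SimRead(
                id=f"r{read_no:07d}",
                seq=seq + "A" * int(rng.integers(8, 21)),
                contig=name,
                strand=strand,
                anchor=anchor,
                umi="".join(rng.choice(_BASES, size=8)),
                is_spike=True,
            )
        )
        read_no += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "pi", "delta", "true_pr", "n_reads", "n_molecules", "n_recent"],
    )
    return reads, truth


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            name = f"{r.id}_{r.barcode}_{r.umi}"
            fh.write(f"@{name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# perturbation time courses


@dataclass
class PerturbationScenario:
    """Piecewise-constant rate changes after an acute depletion at t = 0.

    ``shutdown_factor`` multiplies every gene's degradation rate from
    t = 0 on; at ``adaptation_onset`` minutes the transcription rate is
    multiplied by ``adaptation_factor``. ``onset_jitter_sd`` adds
    per-gene Gaussian jitter to the onset (floored at 0) to plant
    gene-to-gene adaptation-timing differences.
    """

    name: str
    shutdown_factor: float = 1.0
    adaptation_onset: float = 0.0
    adaptation_factor: float = 1.0
    onset_jitter_sd: float = 0.0
    times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 241.0, 5.0)
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.shutdown_factor <= 1.0):
            raise ValueError("shutdown_factor must be in (0, 1]")
        if not (0.0 < self.adaptation_factor <= 1.0):
            raise ValueError("adaptation_factor must be in (0, 1]")
        if self.adaptation_onset < 0:
            raise ValueError("adaptation_onset must be >= 0")
        self.times = np.asarray(self.times, dtype=float)


def scenario_library(name: str | None = None):
    """Named depletion presets ordered along the 5'-3' decay pathway.

    The downstream exonuclease preset ('xrn1-like') is a near-complete
    degradation shutdown with late transcriptional adaptation; upstream
    factors ('dcp2-like' decapping, 'not1-like' deadenylation scaffold)
    shut degradation down progressively less but trigger adaptation
    earlier (onsets 70/52/33 min). 'wildtype' is the identity scenario.
    """
    presets = {
        "wildtype": PerturbationScenario("wildtype"),
        "xrn1-like": PerturbationScenario(
            "xrn1-like", shutdown_factor=0.05, adaptation_onset=70.0,
            adaptation_factor=0.5,
        ),
        "dcp2-like": PerturbationScenario(
            "dcp2-like", shutdown_factor=0.40, adaptation_onset=52.0,
            adaptation_factor=0.5,
        ),
        "not1-like": PerturbationScenario(
            "not1-like", shutdown_factor=0.70, adaptation_onset=33.0,
            adaptation_factor=0.5,
        ),
    }
    if name is None:
        return presets
    if name not in presets:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(presets)}")
    return presets[name]


def scenario_from_file(path) -> PerturbationScenario:
    """Load a perturbation scenario from a YAML (or JSON) mapping.

    Recognized keys mirror :class:`PerturbationScenario`; a ``preset``
    key starts from a named library entry and overrides fields on top.
    """
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh) or {}
    if "preset" in spec:
        base = scenario_library(spec.pop("preset"))
        fields = {
            "name": base.name,
            "shutdown_factor": base.shutdown_factor,
            "adaptation_onset": base.adaptation_onset,
            "adaptation_factor": base.adaptation_factor,
            "onset_jitter_sd": base.onset_jitter_sd,
            "times": base.times,
        }
    else:
        fields = {"name": spec.get("name", "custom")}
    fields.update(spec)
    if "times" in fields:
        fields["times"] = np.asarray(fields["times"], dtype=float)
    return PerturbationScenario(**fields)


def _advance(r0: float, pi: float, rate: float, dt: float) -> float:
    """Exact solution of dR/dt = pi - rate * R over a constant segment."""
    if dt <= 0:
        return r0
    if rate <= 0:
        return r0 + pi * dt
    r_ss = pi / rate
    return r_ss + (r0 - r_ss) * math.exp(-rate * dt)


def _total_at(t: float, r0: float, events: list[tuple[float, float, float]],
              gamma: float) -> float:
    """R(t) for piecewise-constant (pi, delta) given as (start, pi, delta)."""
    r = r0
    for i, (start, pi, delta) in enumerate(events):
        end = events[i + 1][0] if i + 1 < len(events) else math.inf
        lo, hi = max(start, 0.0), min(end, t)
        if hi > lo:
            r = _advance(r, pi, delta + gamma, hi - lo)
        if end >= t:
            break
    return r


def _recent_at(t: float, events: list[tuple[float, float, float]],
               gamma: float, t_label: float, t0: float) -> float:
    """Labeled molecules at ``t`` from a pulse over [t - t_label, t].

    Exact integral of production times survival over the effective
    labeling window (pulse minus conversion lag), honoring every rate
    segment it spans.
    """
    a = t - (t_label - t0)
    if a >= t:
        return 0.0
    total = 0.0
    decay_after = 0.0
    # walk segments intersecting [a, t] from latest to earliest
    bounds = sorted({a, t} | {s for s, _, _ in events if a < s < t})
    for lo, hi in reversed(list(zip(bounds[:-1], bounds[1:]))):
        pi, delta = events[0][1], events[0][2]
        for start, p, d in events:
            if start <= lo:
                pi, delta = p, d
        rate = delta + gamma
        dt = hi - lo
        if rate > 0:
            seg = pi * (1.0 - math.exp(-rate * dt)) / rate
        else:
            seg = pi * dt
        total += seg * math.exp(-decay_after)
        decay_after += rate * dt
    return total


def simulate_timecourse(
    scenario: PerturbationScenario,
    config: SimConfig,
    noise_sd: float = 0.0,
) -> dict[str, Trajectory]:
    """Per-gene total and recently-transcribed trajectories.

    Before t = 0 each gene sits at its steady state pi/(delta + gamma).
    The shutdown and adaptation events define piecewise-constant rates;
    total mRNA follows the exact segment-wise exponential solution and
    the recently-transcribed level is the exact labeled-molecule count
    for a pulse of ``config.t_label`` minutes ending at each sample
    time. Optional multiplicative log-normal noise emulates measurement
    scatter.
    """
    rng = np.random.default_rng(config.seed)
    out = {}
    for gene in config.genes:
        onset = scenario.adaptation_onset
        if scenario.onset_jitter_sd > 0:
            onset = max(0.0, onset + rng.normal(0.0, scenario.onset_jitter_sd))
        delta_post = gene.delta * scenario.shutdown_factor
        pi_post = gene.pi * scenario.adaptation_factor
        events = [
            (-math.inf, gene.pi, gene.delta),
            (0.0, gene.pi, delta_post),
            (onset, pi_post, delta_post),
        ]
        if scenario.shutdown_factor == 1.0 and scenario.adaptation_factor == 1.0:
            events = [(-math.inf, gene.pi, gene.delta)]
        r0 = gene.pi / (gene.delta + config.gamma)
        total = np.array([_total_at(t, r0, events, config.gamma) for t in scenario.times])
        recent = np.array([
            _recent_at(t, events, config.gamma, config.t_label, config.t0)
            for t in scenario.times
        ])
        if noise_sd > 0:
            total = total * np.exp(rng.normal(0.0, noise_sd, total.shape))
            recent = recent * np.exp(rng.normal(0.0, noise_sd, recent.shape))
        with np.errstate(divide="ignore", invalid="ignore"):
            p_r = np.where(total > 0, recent / total, 0.0)
        out[gene.gene_id] = Trajectory(
            transcript_id=gene.gene_id,
            times=scenario.times.copy(),
            total=total,
            recent=recent,
            p_r=p_r,
        )
    return out
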