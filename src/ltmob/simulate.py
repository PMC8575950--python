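"""Stochastic simulator of headful packaging and transduction.

The mechanism simulated: on induction, a pac-type prophage either excises
and produces infectious phage, or remains integrated and serves as the
substrate for in situ packaging — the terminase initiates at the embedded
pac site and fills successive capsids processively along the chromosome
(lateral transduction, LT).  Independently, packaging series may initiate at
pseudo-pac (ppac) chromosomal sites that imperfectly mimic the pac sequence
(generalized transduction, GT), at much lower efficiency.  A delivered
chromosomal fragment recombines into the recipient with a fixed probability;
phage particles lysogenise recipients with a fixed probability.

Series length follows 1 + Geometric(q) truncated at the phage's maximum
headful number: q is the probability that each additional processive headful
is packaged, so a marker in headful k transfers with expected frequency
proportional to q^(k-1).  This one-parameter law is a modelling choice — the
simplest decaying mechanism consistent with the observed per-headful decline
of LT transfer frequencies.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` streams, so identical parameters reproduce
identical lysates and outcomes bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .annotations import AnnotatedGenome
from .geometry import (
    AttBSite,
    CircularInterval,
    GenomicLocus,
    ProphageModel,
    headful_windows,
    locus_headful_range,
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PpacSite:
    """A pseudo-pac site: position, packaging direction, and the efficiency
    of terminase initiation relative to a bona fide pac site."""

    position: int
    direction: int
    relative_efficiency: float

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise SimulationError("ppac direction must be +1 or -1")
        if not 0.0 <= self.relative_efficiency <= 1.0:
            raise SimulationError("relative_efficiency must be in [0, 1]")


@dataclass
class SimulationParams:
    n_donors: int = 10_000
    induction_fraction: float = 1.0
    p_in_situ: float = 0.1  # packaging initiates on the integrated prophage (LT)
    series_continuation: float = 0.7  # q: each further processive headful packaged
    ppac_sites: list[PpacSite] = field(default_factory=list)
    recombination_prob: float = 1.0
    lysogenisation_prob: float = 0.7
    particles_per_donor: int = 10  # packaging-series slots per induced donor
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "induction_fraction",
            "p_in_situ",
            "series_continuation",
            "recombination_prob",
            "lysogenisation_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimulationError(f"{name} must be a probability, got {value}")
        if self.n_donors <= 0 or self.particles_per_donor <= 0:
            raise SimulationError("counts must be positive")


@dataclass(frozen=True)
class Particle:
    mode: str  # "phage" | "LT" | "GT"
    packaged: CircularInterval  # chromosomal content for LT/GT particles
    series_index: int  # headful number within its packaging series


@dataclass
class Lysate:
    particles: list[Particle]
    genome_length: int
    site: AttBSite
    model: ProphageModel
    params: SimulationParams
    n_induced: int

    def counts(self) -> dict[str, int]:
        out = {"phage": 0, "LT": 0, "GT": 0}
        for p in self.particles:
            out[p.mode] += 1
        return out


@dataclass
class TransductionOutcome:
    per_marker: dict[str, tuple[int, float]]  # marker → (events, TE/donor)
    per_headful_profile: dict[int, float]
    marker_headfuls: dict[str, Optional[int]]
    lysogens_per_donor: float
    n_donors: int


@dataclass
class HeadfulProfile:
    headfuls: list[int]
    frequencies: list[float]
    non_monotonic: bool


def _series_lengths(rng: np.random.Generator, n_series: int, q: float, n_max: int) -> np.ndarray:
    if n_series == 0:
        return np.zeros(0, dtype=np.int64)
    if q >= 1.0:
        return np.full(n_series, n_max, dtype=np.int64)
    if q <= 0.0:
        return np.ones(n_series, dtype=np.int64)
    # geometric(p) counts trials to first success: P(S >= k) = q^(k-1) with p = 1-q
    return np.minimum(rng.geometric(1.0 - q, size=n_series), n_max)


def _lt_chromosomal_window(
    window: CircularInterval, site: AttBSite, carryover: int
) -> Optional[CircularInterval]:
    """Chromosomal portion of LT headful 1 after phage-DNA carryover."""
    if carryover == 0:
        return window
    if carryover >= window.length:
        return None
    length = window.length - carryover
    if site.direction == +1:
        start = (window.start + carryover) % window.genome_length
    else:
        start = window.start
    return CircularInterval(start, length, window.genome_length)


def simulate_lysate(
    genome: AnnotatedGenome,
    site: AttBSite,
    model: ProphageModel,
    params: SimulationParams,
) -> Lysate:
    """Simulate one induction: the particle content of the resulting lysate.

    Each induced donor contributes ``particles_per_donor`` packaging-series
    initiations.  A slot starts an LT series on the integrated prophage with
    probability ``p_in_situ`` and otherwise yields an infectious phage
    particle; GT series additionally initiate at each ppac site with its
    relative efficiency per slot.
    """
    registered = {(s.site_id, s.position, s.direction) for s in genome.attb_sites}
    if (site.site_id, site.position, site.direction) not in registered:
        raise SimulationError(
            f"site {site.site_id!r} not in the genome's attB registry"
        )
    L = genome.length
    rng = np.random.default_rng([params.seed, 0])
    n_induced = int(rng.binomial(params.n_donors, params.induction_fraction))
    slots = n_induced * params.particles_per_donor
    q = params.series_continuation

    particles: list[Particle] = []

    n_lt_series = int(rng.binomial(slots, params.p_in_situ))
    n_phage = slots - n_lt_series
    lt_windows = headful_windows(site, model, L)
    hf1_chrom = _lt_chromosomal_window(lt_windows[0], site, model.hf1_phage_carryover)
    lengths = _series_lengths(rng, n_lt_series, q, min(model.n_max, len(lt_windows)))
    for s_len in lengths:
        for k in range(1, int(s_len) + 1):
            window = hf1_chrom if k == 1 else lt_windows[k - 1]
            if window is None:
                continue
            particles.append(Particle("LT", window, k))

    for ppac in params.ppac_sites:
        n_gt_series = int(rng.binomial(slots, ppac.relative_efficiency))
        gt_site = AttBSite(f"ppac@{ppac.position}", ppac.position, ppac.direction)
        gt_windows = headful_windows(gt_site, model, L)
        gt_lengths = _series_lengths(rng, n_gt_series, q, min(model.n_max, len(gt_windows)))
        for s_len in gt_lengths:
            for k in range(1, int(s_len) + 1):
                particles.append(Particle("GT", gt_windows[k - 1], k))

    phage_interval = CircularInterval(
        site.position, min(model.headful_size, L), L
    )
    particles.extend(Particle("phage", phage_interval, 1) for _ in range(n_phage))

    return Lysate(particles, L, site, model, params, n_induced)


def simulate_transduction(
    lysate: Lysate,
    markers: Sequence[GenomicLocus],
    params: Optional[SimulationParams] = None,
) -> TransductionOutcome:
    """Infect recipients with the lysate and count marker transfers.

    A marker transfers when a transducing particle's packaged interval fully
    contains its span and a Bernoulli(recombination_prob) recombination into
    the recipient chromosome succeeds.  Phage particles contribute new
    lysogens with probability ``lysogenisation_prob``.  Frequencies are per
    donor cell.
    """
    params = params or lysate.params
    rng = np.random.default_rng([params.seed, 1])
    L = lysate.genome_length
    for m in markers:
        if m.span.genome_length != L:
            raise SimulationError(f"marker {m.locus_id} not on the donor genome")

    transducing = [p for p in lysate.particles if p.mode != "phage"]
    starts = np.array([p.packaged.start for p in transducing], dtype=np.int64)
    lens = np.array([p.packaged.length for p in transducing], dtype=np.int64)

    per_marker: dict[str, tuple[int, float]] = {}
    marker_headfuls: dict[str, Optional[int]] = {}
    per_headful: dict[int, float] = {}
    for marker in markers:
        if starts.size:
            offsets = (marker.span.start - starts) % L
            containing = int(np.count_nonzero(offsets + marker.span.length <= lens))
        else:
            containing = 0
        events = int(rng.binomial(containing, params.recombination_prob))
        freq = events / params.n_donors
        per_marker[marker.locus_id] = (events, freq)
        hf_range = locus_headful_range(lysate.site, marker, lysate.model, L)
        hf = hf_range[0] if hf_range is not None and hf_range[0] == hf_range[1] else None
        marker_headfuls[marker.locus_id] = hf
        if hf is not None:
            per_headful[hf] = per_headful.get(hf, 0.0) + freq

    n_phage = sum(1 for p in lysate.particles if p.mode == "phage")
    lysogens = int(rng.binomial(n_phage, params.lysogenisation_prob))

    return TransductionOutcome(
        per_marker=per_marker,
        per_headful_profile=per_headful,
        marker_headfuls=marker_headfuls,
        lysogens_per_donor=lysogens / params.n_donors,
        n_donors=params.n_donors,
    )


def estimate_headful_profile(outcome: TransductionOutcome) -> HeadfulProfile:
    """Ordered per-headful transfer-frequency profile from an outcome.

    Requires the markers to have covered distinct headful windows, one each;
    flags (but does not reject) empirically non-monotonic noise.
    """
    headfuls = [hf for hf in outcome.marker_headfuls.values() if hf is not None]
    if not headfuls:
        raise SimulationError("no marker mapped to a headful window")
    if len(headfuls) != len(set(headfuls)) or len(headfuls) != len(outcome.marker_headfuls):
        raise SimulationError("markers must cover distinct headful windows")
    order = sorted(outcome.per_headful_profile)
    freqs = [outcome.per_headful_profile[k] for k in order]
    non_monotonic = any(b > a for a, b in zip(freqs, freqs[1:]))
    return HeadfulProfile(order, freqs, non_monotonic)


def _profile_loglik(log_q: float, counts: np.ndarray) -> float:
    """Profile log-likelihood of q under c_k ~ Poisson(A q^(k-1)), A profiled out."""
    k = np.arange(len(counts))
    c_total = counts.sum()
    s = np.exp(k * log_q).sum()
    t = float((counts * k).sum())
    return float(c_total * (math.log(c_total / s)) + t * log_q - c_total)


def recover_continuation_probability(
    counts: Sequence[float], n_max: Optional[int] = None
) -> tuple[float, float]:
    """Maximum-likelihood continuation probability q from per-headful counts.

    ``counts[k-1]`` is the number of transfer events observed for a marker in
    headful k.  Under the truncated-geometric series-length law the expected
    counts decay as q^(k-1); the MLE solves T/C = q S'(q)/S(q) and the
    standard error comes from the observed information of the profile
    log-likelihood.  Boundary cases: a flat profile gives q = 1, all events
    in headful 1 give q = 0 (both with SE reported as nan).
    """
    c = np.asarray(list(counts), dtype=float)
    if n_max is not None:
        c = c[:n_max]
    if c.ndim != 1 or len(c) < 2:
        raise SimulationError("need counts for at least two headfuls")
    if np.any(c < 0):
        raise SimulationError("counts must be non-negative")
    c_total = c.sum()
    if c_total == 0:
        raise SimulationError("degenerate profile: all counts zero")
    m = len(c)
    k = np.arange(m)
    t = float((c * k).sum())
    ratio = t / c_total
    if ratio == 0.0:
        return 0.0, float("nan")

    def mean_index(q: float) -> float:
        w = q ** k
        return float((k * w).sum() / w.sum())

    if ratio >= (m - 1) / 2.0:
        return 1.0, float("nan")
    q_hat = float(optimize.brentq(lambda q: mean_index(q) - ratio, 1e-12, 1.0 - 1e-12))

    # observed information of the profile log-likelihood, numerically
    h = 1e-5
    lq = math.log(q_hat)
    d2 = (
        _profile_loglik(lq + h, c) - 2.0 * _profile_loglik(lq, c) + _profile_loglik(lq - h, c)
    ) / h**2
    # information w.r.t. q itself: l''(q) = (l''(log q) - l'(log q)) / q^2;
    # at the MLE l'(log q) = 0, so the first-derivative term vanishes
    info = -d2 / q_hat**2
    se = 1.0 / math.sqrt(info) if info > 0 else float("nan")
    return q_hat, se
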