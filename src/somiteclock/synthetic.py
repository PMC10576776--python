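"""Stochastic amplitude-threshold generators for segmentation-clock data.

The generative model: during each clock cycle a group of presomitic
mesoderm cells produces a collective oscillation whose amplitude A is drawn
from a log-normal distribution, A = s * exp(mu + sigma * Z) with Z standard
normal and s > 0 a multiplicative environment factor (1 = favorable; low
temperature or hypoxia lower s).  The cycle yields an intact somite
boundary iff A >= theta, an amplitude threshold; otherwise the boundary is
defected.  Cycles, and the left and right sides of an embryo, are mutually
independent draws, which is what makes the resulting binary phenotype
series look like coin flips along the axis.

Three generators emulate the three data modalities downstream modules
consume: binary boundary-phenotype tables, reporter kymographs carrying
posterior-to-anterior traveling waves with per-cycle amplitudes, and
striped two-gene per-cell transcript fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kymo import Kymograph

__all__ = [
    "ClockSimParams",
    "SyntheticEmbryo",
    "KymoSynthParams",
    "CellFieldParams",
    "simulate_boundary_outcomes",
    "analytic_defect_probability",
    "threshold_for_defect_probability",
    "synthesize_kymograph",
    "synthesize_cell_field",
]

SIDES = ("L", "R")

#: Cycle c (1-based, counted from the 7-somite stage) determines boundary 10 + c.
FIRST_BOUNDARY = 11


@dataclass(frozen=True)
class ClockSimParams:
    """Parameters of the amplitude-threshold model.

    The default 20 cycles cover somite boundaries 11-30, the range scored in
    the phenotype tables.  ``lr_rho`` optionally correlates the left and
    right amplitude draws of an embryo; the default 0 reflects the empirical
    finding that the two sides are approximately independent in clock
    mutants.
    """

    n_cycles: int = 20
    mu: float = 0.0
    sigma: float = 0.5
    theta: float = 1.0
    env_scale: float = 1.0
    n_embryos: int = 50
    seed: int = 0
    condition: str = "sim"
    lr_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.env_scale <= 0:
            raise ValueError("env_scale must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not -1.0 <= self.lr_rho <= 1.0:
            raise ValueError("lr_rho must lie in [-1, 1]")


@dataclass
class SyntheticEmbryo:
    """Ground truth for one simulated embryo: per-side amplitude and
    phenotype series over cycles 1..n_cycles (phenotype 1 iff A < theta)."""

    embryo_id: str
    amplitudes: dict  # side -> ndarray of A_c
    phenotypes: dict  # side -> ndarray of {0 intact, 1 defected}


def analytic_defect_probability(params: ClockSimParams) -> float:
    """Closed-form per-cycle defect probability P(A < theta).

    A is log-normal, so P(A < theta) = Phi((ln theta - ln s - mu) / sigma);
    0 when theta <= 0 (amplitudes are strictly positive).
    """
    if params.theta <= 0:
        return 0.0
    z = (np.log(params.theta) - np.log(params.env_scale) - params.mu) / params.sigma
    return float(norm.cdf(z))


def threshold_for_defect_probability(
    p: float, mu: float = 0.0, sigma: float = 0.5, env_scale: float = 1.0
) -> float:
    """Threshold theta at which the per-cycle defect probability equals p."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    return float(env_scale * np.exp(mu + sigma * norm.ppf(p)))


def simulate_boundary_outcomes(
    params: ClockSimParams,
) -> tuple[list[SyntheticEmbryo], pd.DataFrame]:
    """Draw per-cycle amplitudes for every embryo and side, threshold them,
    and tabulate the resulting boundary phenotypes.

    Cycle c maps to somite boundary 10 + c.  Returns both the ground-truth
    embryos (amplitudes included) and the derived boundary table with
    columns embryo_id, side, boundary_index, phenotype (0 intact /
    1 defected), condition.  Identical params (seed included) give
    bit-identical outputs: each embryo draws from its own child stream of
    the root seed, so outputs are stable under reordering.
    """
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(params.n_embryos)
    embryos: list[SyntheticEmbryo] = []
    rows: list[tuple] = []
    boundaries = FIRST_BOUNDARY - 1 + np.arange(1, params.n_cycles + 1)
    for i, child in enumerate(children):
        rng_l, rng_r = (np.random.default_rng(s) for s in child.spawn(2))
        z_l = rng_l.standard_normal(params.n_cycles)
        z_eps = rng_r.standard_normal(params.n_cycles)
        z_r = params.lr_rho * z_l + np.sqrt(1.0 - params.lr_rho**2) * z_eps
        amp = {
            "L": params.env_scale * np.exp(params.mu + params.sigma * z_l),
            "R": params.env_scale * np.exp(params.mu + params.sigma * z_r),
        }
        pheno = {s: (amp[s] < params.theta).astype(int) for s in SIDES}
        eid = f"e{i:04d}"
        embryos.append(SyntheticEmbryo(eid, amp, pheno))
        for s in SIDES:
            for b, ph in zip(boundaries, pheno[s]):
                rows.append((eid, s, int(b), int(ph), params.condition))
    table = pd.DataFrame(
        rows, columns=["embryo_id", "side", "boundary_index", "phenotype", "condition"]
    )
    return embryos, table


@dataclass(frozen=True)
class KymoSynthParams:
    """Parameters of the synthetic reporter kymograph.

    The waveform is a raised cosine traveling from posterior (column 0)
    toward anterior at ``speed_um_per_min``; at any fixed position the local
    period is wavelength / speed.  ``amplitudes`` are the per-cycle
    trough-to-peak amplitudes planted at the determination front
    (``front_fraction`` of the spatial extent from the posterior edge);
    cycle windows are counted from ``seven_somite_frame``.  Defaults mimic
    the acquisition used for the real reporters: 5-min frames, 2.6-um
    pixels, a clock period of 12 frames (60 min).
    """

    n_frames: int = 200
    n_px: int = 200
    frame_interval_min: float = 5.0
    px_size_um: float = 2.6
    baseline: float = 100.0
    wavelength_um: float = 260.0
    speed_um_per_min: float = 260.0 / 60.0
    amplitudes: tuple = tuple(np.ones(15))
    noise_sd: float = 0.0
    front_fraction: float = 0.5
    seven_somite_frame: int = 0
    temperature_label: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.front_fraction < 1.0:
            raise ValueError("front_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.n_frames, self.n_px) < 2:
            raise ValueError("kymograph dimensions too small")

    @property
    def period_min(self) -> float:
        return self.wavelength_um / self.speed_um_per_min

    @property
    def period_frames(self) -> float:
        return self.period_min / self.frame_interval_min


def synthesize_kymograph(kp: KymoSynthParams) -> tuple[Kymograph, np.ndarray]:
    """Render a kymograph carrying planted per-cycle wave amplitudes.

    Intensity is I(x, t) = B + A_c(x, t) * (1 + cos phi(x, t)) / 2 + eps with
    phi a linear traveling-wave phase and eps ~ N(0, noise_sd^2).  Each
    traveling crest carries its own amplitude: the amplitude index switches
    at the wave troughs (phase pi mod 2 pi), where the intensity equals the
    baseline from both sides, so the noiseless signal stays continuous (C1)
    and the trough-to-peak range of cycle c at the front equals A_c exactly
    (the generator contract the round-trip tests rely on).  The phase origin
    places the front at phase -pi/2 at the 7-somite frame, so in each
    period-long detection window the peak sits a quarter period in and the
    trough three quarters in -- both strictly interior.

    Returns the kymograph and the planted amplitude array.
    """
    amps = np.asarray(kp.amplitudes, dtype=float)
    n_cycles = len(amps)
    pf = kp.period_frames
    if kp.n_frames - kp.seven_somite_frame < pf:
        raise ValueError(
            "kymograph too short to contain one full cycle after the "
            "7-somite frame"
        )
    if kp.n_frames - kp.seven_somite_frame < n_cycles * pf:
        raise ValueError(
            f"kymograph holds fewer than {n_cycles} full cycles; extend "
            "n_frames or drop amplitudes"
        )
    t_min = np.arange(kp.n_frames) * kp.frame_interval_min
    x_um = np.arange(kp.n_px) * kp.px_size_um
    x_front = kp.front_fraction * kp.n_px * kp.px_size_um
    t7_min = kp.seven_somite_frame * kp.frame_interval_min
    # phase at (x_front, t7) = -pi/2
    phi0 = -np.pi / 2 - 2 * np.pi * (t7_min * kp.speed_um_per_min - x_front) / kp.wavelength_um
    phi = (
        2 * np.pi
        * (t_min[:, None] * kp.speed_um_per_min - x_um[None, :])
        / kp.wavelength_um
        + phi0
    )
    # wave c (0-based) spans phase [pi + 2 pi (c-1), pi + 2 pi c)
    cycle = np.clip(np.floor((phi - np.pi) / (2 * np.pi)).astype(int) + 1, 0, n_cycles - 1)
    data = kp.baseline + amps[cycle] * (1.0 + np.cos(phi)) / 2.0
    if kp.noise_sd > 0:
        rng = np.random.default_rng(kp.seed)
        data = data + rng.normal(0.0, kp.noise_sd, size=data.shape)
    kymo = Kymograph(
        data,
        frame_interval_min=kp.frame_interval_min,
        px_size_um=kp.px_size_um,
        seven_somite_frame=kp.seven_somite_frame,
        temperature_label=kp.temperature_label,
    )
    return kymo, amps


@dataclass(frozen=True)
class CellFieldParams:
    """Parameters of the striped two-gene transcript field.

    Cells are uniform in a PSM rectangle (posterior at x = 0).  Counts are
    Poisson with a cosine-striped rate: gene 1 has per-cell phase jitter
    eta ~ N(0, jitter_sd^2), gene 2 an additional fixed offset
    ``phase_offset`` plus its own independent jitter.  jitter_sd = 0 and
    phase_offset = 0 gives wild-type-like in-phase stripes; large jitter
    emulates the decorrelated mutant expression.  Defaults: a ~500-um PSM
    with 2-3 stripes (200-um wavelength) and ~2000 cells, the scale of one
    imaged embryo.
    """

    n_cells: int = 2000
    psm_length_um: float = 500.0
    psm_width_um: float = 100.0
    wavelength_um: float = 200.0
    modulation: float = 0.9
    mean_count: float = 50.0
    phase_offset: float = 0.0
    jitter_sd: float = 0.0
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation <= 1.0:
            raise ValueError("modulation must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")


def synthesize_cell_field(cp: CellFieldParams) -> pd.DataFrame:
    """Draw a per-cell transcript-count table with striped expression.

    Returns a DataFrame with columns cell_id, x_um, y_um, count_gene1,
    count_gene2; counts are non-negative integers.
    """
    rng = np.random.default_rng(cp.seed)
    x = rng.uniform(0.0, cp.psm_length_um, cp.n_cells)
    y = rng.uniform(0.0, cp.psm_width_um, cp.n_cells)
    eta1 = rng.normal(0.0, cp.jitter_sd, cp.n_cells) if cp.jitter_sd > 0 else 0.0
    eta2 = rng.normal(0.0, cp.jitter_sd, cp.n_cells) if cp.jitter_sd > 0 else 0.0
    base_phase = 2 * np.pi * x / cp.wavelength_um
    rate1 = cp.background + cp.mean_count * (1 + cp.modulation * np.cos(base_phase + eta1))
    rate2 = cp.background + cp.mean_count * (
        1 + cp.modulation * np.cos(base_phase + cp.phase_offset + eta2)
    )
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(cp.n_cells)],
            "x_um": x,
            "y_um": y,
            "count_gene1": rng.poisson(rate1),
            "count_gene2": rng.poisson(rate2),
        }
    )
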