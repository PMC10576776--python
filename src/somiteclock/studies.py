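"""Self-contained simulation studies over the package's own generators.

Each study states a synthetic world, runs the full measurement chain on
it, and returns the summary numbers.  They back the numbered analysis
scripts and the acceptance checks.

``independence_study`` probes the independence null: if each clock cycle
fails independently with probability p, the consecutive-boundary and
left-right phenotype correlations should average out near zero -- the
pattern observed in her7 mutant scoring (p close to 0.45 matches the
observed defect fraction there).

``amplitude_recovery_study`` plants a known defected:intact amplitude-median
ratio into synthetic kymographs and recovers it through the complete
extraction pipeline (front profile, smoothing, windowed trough-to-peak
detection, per-experiment normalization), the end-to-end check that the
measured "percent less" is faithful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import boundaries as bstats
from . import kymo as km
from .synthetic import (
    ClockSimParams,
    KymoSynthParams,
    simulate_boundary_outcomes,
    synthesize_kymograph,
    threshold_for_defect_probability,
)

__all__ = ["independence_study", "amplitude_recovery_study"]


def independence_study(
    n_embryos: int = 111,
    defect_probability: float = 0.45,
    n_cycles: int = 20,
    seed: int = 42,
) -> dict:
    """Simulate embryos with i.i.d. per-cycle failures and measure both
    phenotype correlations.

    The amplitude threshold is placed at the quantile that makes the
    per-cycle defect probability exactly ``defect_probability``, so each
    side is a run of i.i.d. Bernoulli outcomes.  111 embryos give 222
    sides, the sample sizes of the real scoring dataset.  Returns the mean
    per-side consecutive-boundary r, the mean per-embryo left-right r, and
    their standard errors.
    """
    params = ClockSimParams(
        n_cycles=n_cycles,
        mu=0.0,
        sigma=0.5,
        theta=threshold_for_defect_probability(defect_probability, mu=0.0, sigma=0.5),
        env_scale=1.0,
        n_embryos=n_embryos,
        seed=seed,
        condition=f"iid-p{defect_probability}",
    )
    _, table = simulate_boundary_outcomes(params)
    cons = bstats.summarize_correlations(bstats.per_side_consecutive(table))
    lr = bstats.summarize_correlations(bstats.per_embryo_left_right(table))
    return {
        "n_sides": int(cons.values.size) + cons.n_excluded,
        "n_embryos": int(lr.values.size) + lr.n_excluded,
        "mean_consecutive_r": cons.mean,
        "se_consecutive_r": float(cons.values.std(ddof=1) / np.sqrt(cons.values.size)),
        "abs_mean_consecutive_r": abs(cons.mean),
        "mean_left_right_r": lr.mean,
        "se_left_right_r": float(lr.values.std(ddof=1) / np.sqrt(lr.values.size)),
        "abs_mean_left_right_r": abs(lr.mean),
        "empirical_defect_fraction": float(table["phenotype"].mean()),
    }


def _one_experiment(
    exp_id: str,
    n_waves: int,
    ratio: float,
    noise_sd: float,
    spread_sigma: float,
    p_defect: float,
    period_frames: int,
    rng: np.random.Generator,
    seed: int,
) -> pd.DataFrame:
    """Synthesize one kymograph with fate-dependent planted amplitudes and
    run amplitude extraction on it."""
    fates = (rng.random(n_waves) < p_defect).astype(int)  # 1 = defected
    medians = np.where(fates == 1, ratio, 1.0)
    amps = medians * np.exp(spread_sigma * rng.standard_normal(n_waves))
    frame_interval = 60.0 / period_frames  # 60-min clock period
    kp = KymoSynthParams(
        amplitudes=tuple(amps),
        n_frames=n_waves * period_frames + period_frames,
        n_px=200,
        frame_interval_min=frame_interval,
        wavelength_um=260.0,
        speed_um_per_min=260.0 / 60.0,
        noise_sd=noise_sd,
        seed=seed,
        temperature_label="sim",
    )
    kymo, _ = synthesize_kymograph(kp)
    traj = km.locate_front(kymo, kymo.n_px, kp.front_fraction)
    raw = km.extract_front_profile(kymo, traj, width_px=4)
    prof = km.smooth_resample(raw, window=9, order=2, factor=10)
    waves = km.detect_waves(prof, period_frames, n_waves, kymo.seven_somite_frame)
    waves = km.assign_boundaries(waves)
    pheno = pd.DataFrame(
        {
            "embryo_id": exp_id,
            "side": "L",
            "boundary_index": waves["boundary_index"],
            "phenotype": fates,
        }
    )
    return km.attach_phenotypes(waves, pheno, exp_id)


def amplitude_recovery_study(
    n_experiments: int = 15,
    n_waves: int = 15,
    ratio: float = 0.6,
    noise_sd: float = 0.02,
    spread_sigma: float = 0.25,
    p_defect: float = 0.5,
    period_frames: int = 24,
    seed: int = 42,
) -> dict:
    """Plant a defected:intact amplitude-median ratio and recover it
    end-to-end.

    Per experiment, each wave's fate is Bernoulli(``p_defect``) and its
    amplitude log-normal around median 1 (intact) or ``ratio`` (defected)
    with log-spread ``spread_sigma``.  Waves are rendered into a noisy
    kymograph, re-extracted, normalized to the intact mean per experiment,
    pooled, and compared.  Defaults give 225 waves.  Returns the
    comparison report, including ``percent_less`` (planted truth:
    100 * (1 - ratio)).
    """
    root = np.random.SeedSequence(seed)
    records = []
    for i, child in enumerate(root.spawn(n_experiments)):
        s1, s2 = child.spawn(2)
        rng = np.random.default_rng(s1)
        kymo_seed = int(s2.generate_state(1)[0] % (2**31))
        records.append(
            _one_experiment(
                f"exp{i:02d}", n_waves, ratio, noise_sd, spread_sigma,
                p_defect, period_frames, rng, kymo_seed,
            )
        )
    pooled = km.normalize_amplitudes(pd.concat(records, ignore_index=True))
    report = km.compare_amplitude_groups(pooled)
    report["planted_percent_less"] = 100.0 * (1.0 - ratio)
    report["n_waves_total"] = int(len(pooled))
    return report
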