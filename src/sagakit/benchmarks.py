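"""Ground-truth recovery benchmarks run on synthetic data.

These routines generate data with the :mod:`sagakit.synthetic_data`
generators, push it through the analysis modules, and score the results
against the recorded truth.  They are used by the test suite and by
``scripts/acceptance.py``; every routine takes an explicit seed.

Study conditions (sizes, noise levels, effect sizes) are fixed here:

* phantoms: 12-frame movies, 3-8 branches, core 12-16 px, growth
  4.5-6 px/frame, noise 4% of the projected foreground-background
  contrast;
* tracks: 100-frame walks at 2 px/frame dropping to 0.5 px/frame at a
  mid-movie detachment, jitter 0 or 0.25x the pre-detachment speed;
* expression: 3 replicates per group, baseline sd 0.25 log2 units,
  effects of 0.5-4x the baseline sd.
"""

from __future__ import annotations

import numpy as np

from . import imaging, permde, synthetic_data as sd
from .imaging import SegmentationParams
from .permde import PermParams
from .tracking import split_at_event, track_metrics, tracks_from_frame

PHANTOM_NOISE_FRACTION = 0.04  # of projected fg/bg contrast


def _random_phantom_spec(rng: np.random.Generator, n_frames: int = 12,
                         noise_fraction: float = PHANTOM_NOISE_FRACTION
                         ) -> sd.SpheroidPhantomSpec:
    probe = sd.SpheroidPhantomSpec(image_shape=(n_frames, 6, 176, 176),
                                   core_radius=14, noise_sd=0.0, seed=0)
    contrast = probe.projected_contrast
    return sd.SpheroidPhantomSpec(
        image_shape=(n_frames, 6, 176, 176),
        core_radius=float(rng.uniform(12, 16)),
        n_branches=int(rng.integers(3, 9)),
        branch_growth_rate=float(rng.uniform(4.5, 6.0)),
        branch_width=float(rng.uniform(4.5, 6.0)),
        noise_sd=noise_fraction * contrast,
        seed=int(rng.integers(2 ** 31)),
    )


def phantom_recovery(n_phantoms: int = 50, seed: int = 0) -> dict:
    """Branch-count and invasive-radius recovery over random phantoms.

    Returns the fraction of frames with branch count within +/-1 of truth
    and invasive radius within +/-2 px, using the default (graph-cut)
    pipeline.
    """
    rng = np.random.default_rng(seed)
    branch_ok, radius_ok = [], []
    for _ in range(n_phantoms):
        spec = _random_phantom_spec(rng)
        stack, truth = sd.generate_spheroid_stack(spec)
        table = imaging.feature_timecourse(stack)
        branch_ok.extend(
            np.abs(table.branch_count.to_numpy() - truth.true_branch_count) <= 1)
        radius_ok.extend(
            np.abs(table.invasive_radius.to_numpy()
                   - truth.true_invasive_radius) <= 2.0)
    return {
        "branch_within_1": float(np.mean(branch_ok)),
        "radius_within_2px": float(np.mean(radius_ok)),
        "n_frames": len(branch_ok),
    }


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return 2.0 * (a & b).sum() / max(a.sum() + b.sum(), 1)


def graphcut_threshold_dice(n_phantoms: int = 3, seed: int = 0) -> dict:
    """Dice agreement of graph-cut vs global-threshold segmentation.

    Runs on the raw standard-deviation projections of near-noiseless
    phantoms, which are genuinely bimodal (two-valued up to 1% noise):
    there the smoothness term has nothing to repair and the two methods
    should coincide.  (Gaussian pre-smoothing would blur the step edge
    into a ramp and reintroduce ambiguous boundary pixels.)
    """
    rng = np.random.default_rng(seed)
    dices = []
    for _ in range(n_phantoms):
        spec = _random_phantom_spec(rng, n_frames=6, noise_fraction=0.01)
        stack, _ = sd.generate_spheroid_stack(spec)
        series = imaging.std_project(stack)
        gc = imaging.segment(series, SegmentationParams(method="graphcut"))
        th = imaging.segment(series, SegmentationParams(method="threshold"))
        dices.append(_dice(gc.data, th.data))
    return {"dice_min": float(min(dices)), "dice_mean": float(np.mean(dices)),
            "n": n_phantoms}


def analytic_shape_features() -> dict:
    """Features of ideal rasterised shapes: a disk and a square."""
    yy, xx = np.mgrid[0:96, 0:96]
    disk = ((yy - 48) ** 2 + (xx - 48) ** 2 <= 20 ** 2)[None]
    square = np.zeros((1, 80, 80), bool)
    square[0, 20:60, 20:60] = True
    params = SegmentationParams()
    d = imaging.compute_features(disk, params).iloc[0]
    s = imaging.compute_features(square, params).iloc[0]
    return {
        "disk_circularity": float(d.circularity),
        "disk_invasive_radius": float(d.invasive_radius),
        "disk_branch_count": int(d.branch_count),
        "square_circularity": float(s.circularity),
    }


def track_path_vs_displacement(n_tracks: int = 1000, seed: int = 0) -> dict:
    """Triangle-inequality check over random walks."""
    rng = np.random.default_rng(seed)
    ok = 0
    for i in range(n_tracks):
        n = int(rng.integers(5, 60))
        xy = np.cumsum(rng.normal(0, 2, size=(n, 2)), axis=0)
        from .tracking import Track
        m = track_metrics(Track(i, np.arange(n), xy[:, 0], xy[:, 1]))
        ok += m.path_length >= m.displacement - 1e-9
    return {"fraction_path_ge_displacement": ok / n_tracks, "n": n_tracks}


def speed_ratio_recovery(n_tracks: int = 100, noise_sd: float = 0.0,
                         seed: int = 0) -> dict:
    """Recovered pre/post speed ratio of simulated 4:1 detachment tracks.

    Uses the displacement-based (net) velocity on ballistic tracks: with
    positional jitter, path-length-based speed is biased upward when the
    true step is small relative to the jitter, while the net velocity of a
    straight track is essentially unbiased.
    """
    ratios = []
    for i in range(n_tracks):
        spec = sd.TrackSimSpec(n_frames=101, speed_pre=2.0, speed_post=0.5,
                               detachment_frame=50, persistence=1.0,
                               noise_sd=noise_sd, seed=seed * 100_003 + i)
        tr = tracks_from_frame(sd.generate_tracks(spec).tracks)[0]
        split = split_at_event(tr, 50)
        ratios.append(split.pre.net_velocity / split.post.net_velocity)
    return {"mean_ratio": float(np.mean(ratios)), "true_ratio": 4.0,
            "n": n_tracks}


def sampled_vs_exhaustive_deviation(n_genes: int = 50, seed: int = 0) -> dict:
    """Pool-scheme sampling accuracy on the reduced 2-replicate design.

    With 2 replicates per group there are 4 + 4 difference pairs and
    C(8, 4) = 70 role assignments; the B=500 sampled p-value is compared
    with the exhaustive one, in units of the binomial standard error.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    treat = rng.normal(0.3, 1.0, size=(n_genes, 4))
    ctrl = rng.normal(0.0, 1.0, size=(n_genes, 4))
    pairs = permde.DifferencePairs(pd.Index(range(n_genes)), treat, ctrl,
                                   "leader")
    p_ex = permde.permutation_p(pairs, PermParams(scheme="pool",
                                                  exhaustive=True)).to_numpy()
    p_s = permde.permutation_p(pairs, PermParams(scheme="pool", B=500,
                                                 seed=seed)).to_numpy()
    se = np.sqrt(p_ex * (1 - p_ex) / 500) + 1e-9
    dev = np.abs(p_s - p_ex) / (se + 2 / 70)
    return {"max_deviation_se_units": float(dev.max()), "n_genes": n_genes,
            "n_assignments": 70}


def type1_error(n_genes: int = 2000, seeds=(0, 1, 2)) -> dict:
    """Global-null selection rate at alpha = 0.05, averaged over seeds and
    both test directions."""
    rates = []
    for seed in seeds:
        spec = sd.ExpressionSimSpec(n_genes=n_genes, delta=0.0, f_null=1.0,
                                    f_leader_up=0.0, f_follower_up=0.0,
                                    f_artifact=0.0, seed=seed + 17)
        mat, design, _ = sd.generate_expression(spec)
        res = permde.run_de(mat, design, PermParams(seed=seed))
        rates.append(float(res.selected_leader.mean()))
        rates.append(float(res.selected_follower.mean()))
    return {"type1_rate": float(np.mean(rates)), "per_run": rates,
            "n_genes": n_genes, "n_seeds": len(seeds)}


def power_curve(delta_multiples=(0.5, 1.0, 2.0), n_genes: int = 400,
                seed: int = 0) -> dict:
    """Selection rate of planted leader-up genes at increasing effect size
    (multiples of the baseline sd)."""
    baseline_sd = 0.25
    powers = []
    for mult in delta_multiples:
        spec = sd.ExpressionSimSpec(n_genes=n_genes, delta=mult * baseline_sd,
                                    baseline_sd=baseline_sd, f_null=0.5,
                                    f_leader_up=0.5, f_follower_up=0.0,
                                    f_artifact=0.0, seed=seed + 31)
        mat, design, truth = sd.generate_expression(spec)
        res = permde.run_de(mat, design, PermParams(seed=seed))
        powers.append(float(
            res.selected_leader[truth == "leader_up"].mean()))
    return {"delta_multiples": list(delta_multiples), "power": powers,
            "n_effect_genes": n_genes // 2}


def artifact_exclusion(n_genes: int = 400, seed: int = 0) -> dict:
    """Selection rate of photoconversion-artifact genes relative to matched
    pure leader-up genes with the same effect size (4x baseline sd)."""
    spec = sd.ExpressionSimSpec(n_genes=n_genes, delta=1.0, baseline_sd=0.25,
                                f_null=0.0, f_leader_up=0.5,
                                f_follower_up=0.0, f_artifact=0.5,
                                seed=seed + 47)
    mat, design, truth = sd.generate_expression(spec)
    res = permde.run_de(mat, design, PermParams(seed=seed))
    leader_rate = float(res.selected_leader[truth == "leader_up"].mean())
    artifact_rate = float(res.selected_leader[truth == "artifact"].mean())
    return {"leader_up_rate": leader_rate, "artifact_rate": artifact_rate,
            "ratio": artifact_rate / max(leader_rate, 1e-9),
            "n_each": n_genes // 2}
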