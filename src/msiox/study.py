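"""Reference study workflows: the end-to-end experiments the package is
built around, with one master seed fanning out to every stochastic
component.

Two headline analyses are provided:

* :func:`so2_agreement_study` — synthesize an occlusion-release time
  series through the full forward model and compare per-frame SO2 from
  the ANN against warm-started inverse MC (mean absolute difference and
  Pearson correlation of the two traces);
* :func:`repeat_stability_study` — train ten identically configured
  networks from distinct random initializations and measure the average
  per-sample standard deviation of their predictions on a common held-out
  test set.

Problem sizes are desk-scale: a compact-axis LUT at 4x10^4 photons per
node, 2x10^4 training spectra for the agreement network, 10^4 for the
repeat-stability ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import estimators as est
from . import synth
from .tissue import TissueParams

__all__ = ["StudySeeds", "mid_range_params", "build_study_models",
           "so2_agreement_study", "repeat_stability_study"]

LUT_PHOTONS = 40_000
N_TRAIN_AGREEMENT = 20_000
N_TRAIN_REPEAT = 10_000
N_COMMON_TEST = 1_000
N_FRAMES = 100
# LM training budget for the study networks; validation error on default
# synthetic sets keeps improving intermittently to ~300-700 iterations
TRAIN_KWARGS = dict(max_epochs=800, patience=80)


@dataclass(frozen=True)
class StudySeeds:
    """Deterministic fan-out of one master seed to the study components."""

    master: int

    @property
    def lut(self) -> int:
        return (10 * self.master + 1) % (2**31 - 1)

    @property
    def training(self) -> int:
        return (20 * self.master + 1) % (2**31 - 1)

    @property
    def trace(self) -> int:
        return (30 * self.master + 1) % (2**31 - 1)

    @property
    def fits(self) -> int:
        return (40 * self.master + 1) % (2**31 - 1)

    @property
    def common(self) -> int:
        return (99 * self.master) % (2**31 - 1)

    @property
    def net_base(self) -> int:
        return (100 * self.master) % (2**31 - 1)


def mid_range_params(so2: float = 0.6) -> TissueParams:
    """Tissue parameters at the geometric mid-range of the sampling laws."""
    d = synth.ParamDistribution()

    def gmid(rng):
        return float(np.sqrt(rng[0] * rng[1]))

    t_epi = gmid(d.t_epi)
    return TissueParams(
        t_epi=t_epi, f_mel=gmid(d.mel_amount) / t_epi, f_blood=gmid(d.f_blood),
        s=so2, d_vessel=gmid(d.d_vessel), alpha=gmid(d.alpha),
        beta=0.5 * (d.beta[0] + d.beta[1]))


def build_study_models(seed: int, n_photons: int = LUT_PHOTONS,
                       lut=None) -> synth.ForwardModels:
    """Forward models on the compact-axis LUT (built here unless given)."""
    seeds = StudySeeds(seed)
    if lut is None:
        lut = synth.build_default_lut(n_photons_per_node=n_photons,
                                      seed=seeds.lut)
    return synth.ForwardModels.default(lut)


def synthesize_trace(models: synth.ForwardModels, seed: int,
                     n_frames: int = N_FRAMES):
    """Noisy normalized spectra along the occlusion-release trajectory."""
    seeds = StudySeeds(seed)
    s_traj = synth.occlusion_release_so2(n_frames)
    rng = np.random.default_rng(seeds.trace)
    base = mid_range_params()
    specs = [synth.synthesize_spectrum(replace(base, s=float(s)), models, rng)[0]
             for s in s_traj]
    return specs, 100.0 * s_traj


def so2_agreement_study(models: synth.ForwardModels, seed: int,
                        n_frames: int = N_FRAMES,
                        n_train: int = N_TRAIN_AGREEMENT,
                        n_init: int = 10) -> dict:
    """ANN-vs-inverse-MC agreement on a synthetic occlusion-release trace.

    The ANN is the best-validation H=15 network among ``n_init`` seeded
    trainings on a ``n_train``-spectrum synthetic set (training is repeated
    ten times and the best-performing network applied); the inverse MC
    estimator multi-starts on the first frame and warm-starts thereafter.
    """
    seeds = StudySeeds(seed)
    specs, true = synthesize_trace(models, seed, n_frames)
    train_set = synth.generate_training_set(
        synth.ParamDistribution(), models, n=n_train, seed=seeds.training)
    best = None
    for i in range(n_init):
        model, report = est.train_ann(train_set, hidden=15,
                                      seed=seeds.net_base + i,
                                      **TRAIN_KWARGS)
        if best is None or report.val_mse < best[1].val_mse:
            best = (model, report)
    ann_model, ann_report = best
    ann_trace = est.estimate_timeseries(specs, "ann", ann=ann_model)
    mc_trace, fits = est.estimate_timeseries(specs, "inverse_mc",
                                             models=models, seed=seeds.fits)
    diff = ann_trace - mc_trace
    return {
        "mad": float(np.mean(np.abs(diff))),
        "pearson_r": float(np.corrcoef(ann_trace, mc_trace)[0, 1]),
        "ann_trace": ann_trace, "mc_trace": mc_trace, "true_so2": true,
        "ann_mae_vs_truth": float(np.mean(np.abs(ann_trace - true))),
        "mc_mae_vs_truth": float(np.mean(np.abs(mc_trace - true))),
        "fit_mape_mean": float(np.mean([f.mape for f in fits])),
        "ann_val_rmse": float(np.sqrt(ann_report.val_mse)),
        "n_frames": n_frames,
    }


def repeat_stability_study(models: synth.ForwardModels, seed: int,
                           n_train: int = N_TRAIN_REPEAT,
                           n_common: int = N_COMMON_TEST,
                           n_repeats: int = 10, hidden: int = 15) -> dict:
    """Spread of SO2 predictions across repeatedly trained networks.

    Ten networks share one training set but use distinct random
    initializations; the statistic is the per-sample standard deviation of
    their predictions on a common held-out synthetic test set, averaged.
    """
    seeds = StudySeeds(seed)
    train_set = synth.generate_training_set(
        synth.ParamDistribution(), models, n=n_train, seed=seeds.training)
    common = synth.generate_training_set(
        synth.ParamDistribution(), models, n=n_common, seed=seeds.common)
    nets, reports, _ = est.repeat_train(train_set, hidden=hidden,
                                        n_repeats=n_repeats,
                                        base_seed=seeds.net_base,
                                        **TRAIN_KWARGS)
    preds = np.stack([m.predict(common.X) for m in nets])
    per_sample_std = preds.std(axis=0, ddof=0)
    return {
        "mean_std": float(per_sample_std.mean()),
        "per_sample_std": per_sample_std,
        "val_rmse": [float(np.sqrt(r.val_mse)) for r in reports],
        "n_repeats": n_repeats, "n_common": n_common,
    }
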