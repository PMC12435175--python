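"""Desk-scale study definitions: the concrete synthetic conditions under
which the pipeline's scientific claims are exercised.

Each function sets up one experiment (cohort sizes, noise levels,
training budget), runs it through the public pipeline surface, and
returns plain numbers.  These definitions are shared by the test suite
and by ``scripts/acceptance.py`` so both always measure the same
conditions.  Problem sizes are chosen so every experiment completes in
minutes on a single CPU; see docs/methods.md for the rationale behind
each setting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .adaptation import default_bin_edges, emd, fit_histogram, make_weight_vector
from .cohort import (CohortConfig, MorphologyMap, decode_store, generate_cohort,
                     make_preset, noiseless_config)
from .evaluation import PredictionSet, bootstrap_mae_difference, evaluate
from .models import ModelSpec, build_model, predict
from .pipeline import BenchmarkMatrixSpec, compare_weighted_unweighted, run_benchmark
from .splits import make_calib_split, make_calibfree_split
from .store import SegmentStore
from .training import (MedianBaselineRegressor, TrainConfig, train)

__all__ = [
    "identifiability_experiment", "learning_gate_experiment",
    "calib_gap_experiment", "label_shift_experiment",
    "emd_correlation_experiment", "bootstrap_coverage_experiment",
    "desk_benchmark_experiment",
]

# one compact, CPU-friendly training protocol used across experiments:
# 2.1 s segments, a narrow LeNet-style backbone and a raised learning
# rate compensating for the small number of optimizer steps
_ARCH = "lenet1d"
_SCALE = 0.5
_SEGMENT_SECONDS = 2.1


def _train_config(epochs: int, seed: int) -> TrainConfig:
    return TrainConfig(learning_rate=3e-3, epochs=epochs, effective_batch=64,
                       micro_batch=32, seed=seed)


def _fit_and_eval(store: SegmentStore, split, epochs: int, seed: int,
                  weights=None, extra_eval: dict | None = None) -> dict:
    """Train one model on the split; evaluate on split.test and any extra
    (store, indices) test sets.  Returns reports keyed by test-set name."""
    model = build_model(ModelSpec(architecture=_ARCH, scale=_SCALE), seed=seed)
    result = train(model, store, split, _train_config(epochs, seed),
                   weights=weights)
    out = {"test": evaluate(predict(result.model, store.select(split.test)))}
    for name, (src, idx) in (extra_eval or {}).items():
        out[name] = evaluate(predict(result.model, src.select(idx)))
    out["model"] = result.model
    return out


# ----------------------------------------------------------------------
def identifiability_experiment(seed: int = 0, n_subjects: int = 12,
                               segments_per_subject: int = 3) -> dict:
    """Noiseless cohort -> brute-force waveform inversion, raw and
    z-scored.  Certifies that BP is decodable from pulse shape alone."""
    preset = make_preset("vitaldb", segments_per_subject=segments_per_subject,
                         segment_seconds=_SEGMENT_SECONDS)
    preset = replace(preset, n_subjects=n_subjects)
    config = noiseless_config(preset, seed=seed)
    store = generate_cohort(config)
    out = {}
    for tag, zs in (("raw", False), ("zscored", True)):
        sbp_hat, dbp_hat = decode_store(store, config.morphology, zscore_first=zs)
        out[f"mae_sbp_{tag}"] = float(np.abs(sbp_hat - store.sbp).mean())
        out[f"mae_dbp_{tag}"] = float(np.abs(dbp_hat - store.dbp).mean())
    out["n"] = store.n
    return out


# ----------------------------------------------------------------------
def _low_noise_cohort(seed: int, n_subjects: int = 60,
                      segments_per_subject: int = 8,
                      sbp_shift: float = 0.0, name: str | None = None,
                      noise_sd: float = 0.01, subject_effects: bool = False,
                      morphology: MorphologyMap | None = None) -> CohortConfig:
    if morphology is None:
        morphology = MorphologyMap() if subject_effects else replace(
            MorphologyMap(), subject_delta_sd=0.0, subject_ratio_sd=0.0)
    preset = make_preset("vitaldb", segments_per_subject=segments_per_subject,
                         segment_seconds=_SEGMENT_SECONDS, noise_sd=noise_sd,
                         wander_amp=0.05, hr_jitter_sd=0.01)
    preset = replace(preset, n_subjects=n_subjects,
                     sbp_mean=preset.sbp_mean + sbp_shift,
                     name=name or preset.name)
    return CohortConfig(sites=(preset,), morphology=morphology, seed=seed)


def learning_gate_experiment(seed: int = 0, epochs: int = 60) -> dict:
    """Subject-disjoint training on a low-noise cohort must beat the
    median baseline by a factor of two on both outputs."""
    store = generate_cohort(_low_noise_cohort(seed=seed + 1000))
    split = make_calibfree_split(store, seed=seed)
    y_tr = np.stack([store.sbp[split.train], store.dbp[split.train]], axis=1)
    base = MedianBaselineRegressor().fit(np.zeros((len(y_tr), 1)), y_tr)
    bp = base.predict(np.zeros((len(split.test), 1)))
    base_mae_sbp = float(np.abs(bp[:, 0] - store.sbp[split.test]).mean())
    base_mae_dbp = float(np.abs(bp[:, 1] - store.dbp[split.test]).mean())
    rep = _fit_and_eval(store, split, epochs, seed)["test"]
    return {"mae_sbp": rep.mae_sbp, "mae_dbp": rep.mae_dbp,
            "baseline_mae_sbp": base_mae_sbp, "baseline_mae_dbp": base_mae_dbp,
            "ratio_sbp": rep.mae_sbp / base_mae_sbp,
            "ratio_dbp": rep.mae_dbp / base_mae_dbp,
            "n": int(len(split.test))}


# ----------------------------------------------------------------------
def calib_gap_experiment(n_seeds: int = 10, epochs: int = 30,
                         base_seed: int = 0) -> dict:
    """Subject memorization advantage: with strong subject-level
    morphology effects, a Calib split (subjects shared between train and
    test) must beat a CalibFree split of the same cohort."""
    strong = replace(MorphologyMap(), subject_delta_sd=0.03, subject_ratio_sd=0.10)
    wins = 0
    gaps = []
    for seed in range(base_seed, base_seed + n_seeds):
        store = generate_cohort(_low_noise_cohort(
            seed=seed + 2000, n_subjects=30, noise_sd=0.03, morphology=strong))
        calib = make_calib_split(store, test_frac=0.25, val_frac=0.1,
                                 calib_frac=0.05, seed=seed)
        free = make_calibfree_split(store, test_subject_frac=0.25,
                                    val_subject_frac=0.1,
                                    calib_subject_frac=0.05, seed=seed)
        rep_c = _fit_and_eval(store, calib, epochs, seed)["test"]
        rep_f = _fit_and_eval(store, free, epochs, seed)["test"]
        mae_c = 0.5 * (rep_c.mae_sbp + rep_c.mae_dbp)
        mae_f = 0.5 * (rep_f.mae_sbp + rep_f.mae_dbp)
        wins += mae_c < mae_f
        gaps.append(mae_f - mae_c)
    return {"wins": int(wins), "n_seeds": n_seeds,
            "mean_gap": float(np.mean(gaps))}


# ----------------------------------------------------------------------
def label_shift_experiment(n_seeds: int = 10, epochs: int = 30,
                           shift: float = 20.0, base_seed: int = 0) -> dict:
    """Importance weighting under pure SBP label shift: the target site
    shares the morphology map but its SBP mean sits ``shift`` mmHg
    higher.  Weighted training should lower target-domain SBP MAE."""
    wins = 0
    deltas = []
    for seed in range(base_seed, base_seed + n_seeds):
        src_cfg = _low_noise_cohort(seed=seed + 3000, n_subjects=40,
                                    noise_sd=0.05, subject_effects=True)
        tgt_preset = replace(src_cfg.sites[0], name="target",
                             sbp_mean=src_cfg.sites[0].sbp_mean + shift,
                             n_subjects=25)
        cfg = replace(src_cfg, sites=(src_cfg.sites[0], tgt_preset))
        store = generate_cohort(cfg)
        src_idx = np.flatnonzero(store.site_id == src_cfg.sites[0].name)
        tgt_idx = np.flatnonzero(store.site_id == "target")
        local = store.select(src_idx)
        split = make_calibfree_split(local, seed=seed)
        weights = make_weight_vector(
            local.sbp[split.train], local.dbp[split.train],
            store.sbp[tgt_idx], store.dbp[tgt_idx], tau=1.0)
        extra = {"target": (store, tgt_idx)}
        rep_u = _fit_and_eval(local, split, epochs, seed, extra_eval=extra)
        rep_w = _fit_and_eval(local, split, epochs, seed, weights=weights,
                              extra_eval=extra)
        delta = rep_w["target"].mae_sbp - rep_u["target"].mae_sbp
        wins += delta < 0
        deltas.append(delta)
    return {"wins": int(wins), "n_seeds": n_seeds,
            "mean_delta_sbp": float(np.mean(deltas))}


# ----------------------------------------------------------------------
def emd_correlation_experiment(seed: int = 0, epochs: int = 30,
                               shifts: tuple[float, ...] = (0.0, 8.0, 16.0,
                                                            24.0, 32.0)) -> dict:
    """Train once; evaluate on target sites of graded SBP label shift;
    correlate EMD(train labels, target labels) with OOD MAE."""
    src_cfg = _low_noise_cohort(seed=seed + 4000, n_subjects=40,
                                noise_sd=0.05, subject_effects=True)
    targets = tuple(replace(src_cfg.sites[0], name=f"target{k}",
                            sbp_mean=src_cfg.sites[0].sbp_mean + s,
                            n_subjects=15)
                    for k, s in enumerate(shifts))
    cfg = replace(src_cfg, sites=(src_cfg.sites[0],) + targets)
    store = generate_cohort(cfg)
    src_idx = np.flatnonzero(store.site_id == src_cfg.sites[0].name)
    local = store.select(src_idx)
    split = make_calibfree_split(local, seed=seed)
    extra = {t.name: (store, np.flatnonzero(store.site_id == t.name))
             for t in targets}
    reps = _fit_and_eval(local, split, epochs, seed, extra_eval=extra)
    edges = default_bin_edges()
    h_train = fit_histogram(local.sbp[split.train], edges)
    emds, maes = [], []
    for t in targets:
        h_t = fit_histogram(store.sbp[store.site_id == t.name], edges)
        emds.append(emd(h_train, h_t))
        maes.append(reps[t.name].mae_sbp)
    rho = float(stats.spearmanr(emds, maes).statistic)
    return {"spearman_rho": rho, "emd": emds, "ood_mae_sbp": maes,
            "n_targets": len(targets)}


# ----------------------------------------------------------------------
def bootstrap_coverage_experiment(seed: int = 0, n_replicates: int = 200,
                                  n_segments: int = 200,
                                  n_boot: int = 1000) -> dict:
    """Coverage of the paired bootstrap CI for two equal-skill models:
    the 95% interval should contain 0 in about 95% of replicates."""
    rng = np.random.default_rng(seed)
    contained = 0
    for rep in range(n_replicates):
        ref_bp = rng.normal(120, 15, size=n_segments)
        dbp = rng.normal(65, 10, size=n_segments)
        pred_a = ref_bp + rng.normal(0, 8, size=n_segments)
        pred_b = ref_bp + rng.normal(0, 8, size=n_segments)
        ps_a = PredictionSet(pred_a, dbp, ref_bp, dbp)
        ps_b = PredictionSet(pred_b, dbp, ref_bp, dbp)
        res = bootstrap_mae_difference(ps_a, ps_b, n_boot=n_boot,
                                       seed=seed + rep, outputs=("sbp",))["sbp"]
        contained += res.ci_low <= 0.0 <= res.ci_high
    return {"coverage": contained / n_replicates, "n_replicates": n_replicates}


# ----------------------------------------------------------------------
def desk_benchmark_experiment(seeds: tuple[int, ...] = (0, 1, 2),
                              epochs: int = 25) -> dict:
    """Two-site end-to-end benchmark: train on a Vital-like site
    (calibfree scenario, weighted and unweighted), evaluate in- and
    out-of-distribution on a label-shifted target site."""
    src_cfg = _low_noise_cohort(seed=4321, n_subjects=30, noise_sd=0.05,
                                subject_effects=True)
    target = replace(src_cfg.sites[0], name="shifted",
                     sbp_mean=src_cfg.sites[0].sbp_mean + 20.0, n_subjects=15)
    cohort = replace(src_cfg, sites=(src_cfg.sites[0], target))
    spec = BenchmarkMatrixSpec(
        cohort=cohort,
        cells=[("vitaldb", "calibfree")],
        architectures=[_ARCH],
        test_sites=["shifted"],
        weight_target="shifted",
        train_config=_train_config(epochs, 0),
        model_scale=_SCALE,
        seeds=tuple(seeds))
    table, manifest = run_benchmark(spec)
    if manifest.failures:
        raise RuntimeError(f"benchmark cells failed: {manifest.failures}")
    delta = compare_weighted_unweighted(table)
    id_rows = table[table["test_set"].str.endswith(":test")
                    & ~table["weighted"]]
    ood_rows = table[(table["test_set"] == "shifted") & ~table["weighted"]]
    id_by_seed = id_rows.set_index("seed")["mae_sbp"]
    ood_by_seed = ood_rows.set_index("seed")["mae_sbp"]
    wins = int((id_by_seed < ood_by_seed.loc[id_by_seed.index]).sum())
    return {"table": table, "delta": delta,
            "id_mae_sbp": float(id_by_seed.mean()),
            "ood_mae_sbp": float(ood_by_seed.mean()),
            "id_lt_ood_seeds": wins, "n_seeds": len(seeds)}
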