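"""End-to-end orchestration: simulate -> map -> features -> select/train -> evaluate.

`map_patient` turns one patient's raw series into the twelve biomarker /
anatomical maps (ceT1w, FLAIR, ADC, CBV | OEF, CMRO2, capiPO2, mitoPO2 |
uCBV, MVD, VSI, MTI); `run_experiment` runs the whole study on synthetic
cohorts, including an optional external test cohort acquired under the other
site protocol.

For speed, voxelwise first-pass fitting is restricted to the tumor mask plus
the AIF candidate pool (the highest-peak dR2 voxels of the brain); relative
CBV/CBF/uCBV and the loop metrics are only needed there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import qbold, vam
from .constants import PhysioConstants
from .evaluation import EvaluationReport, evaluate, results_matrix
from .learning import (ModelSpec, make_classical_estimator, predict, relieff_rank,
                       smote_balance, top_fraction, train_classical, train_cnn1d,
                       train_lstm, wrapper_select)
from .learning.models import CLASSICAL_KINDS
from .perfusion import (DeltaR2Curves, compute_cbf, fit_first_pass_many, first_pass_area,
                        select_aif, signal_to_delta_r2, split_gese)
from .phantom import (ClassEffectModel, PatientBundle, default_class_effects,
                      simulate_cohort)
from .radiomics import (CATEGORY_MAPS, assemble_vector, default_biomarker_policies,
                        extract_features, preprocess_map)
from .relaxometry import compute_adc, fit_rate_map

__all__ = ["ExperimentConfig", "ExperimentResult", "map_patient",
           "cohort_feature_table", "run_experiment"]


# ---------------------------------------------------------------------------
# per-patient mapping

def _aif_for(series, brain_mask, n_candidates: int = 300):
    """Screen the brain for arterial candidates and fit/select the AIF."""
    dr2 = signal_to_delta_r2(series, brain_mask)
    peaks = dr2.curves.max(axis=1)
    order = np.argsort(peaks)[::-1][:n_candidates]
    sub = DeltaR2Curves(dr2.times, dr2.curves[order], dr2.invalid[order])
    fits = fit_first_pass_many(sub.curves, sub.times)
    return select_aif(sub, fits)


def map_patient(bundle: PatientBundle, consts: PhysioConstants = PhysioConstants()) -> dict:
    """Compute all twelve maps of one patient from its raw simulated series.

    Returns a dict of full-grid arrays (values outside the tumor mask are 0
    for the perfusion-derived maps) plus the masks.
    """
    phantom = bundle.phantom
    brain, tumor = phantom.brain_mask, phantom.tumor_mask
    shape = brain.shape

    r2s_map = fit_rate_map(bundle.ge_echo, brain)
    r2_map = fit_rate_map(bundle.se_echo, brain)
    adc_map = compute_adc(bundle.dwi, brain)

    if "hybrid" in bundle.dsc:
        ge_series, se_series = split_gese(bundle.dsc["hybrid"])
    else:
        ge_series, se_series = bundle.dsc["ge"], bundle.dsc["se"]

    aif_ge = _aif_for(ge_series, brain)
    aif_se = _aif_for(se_series, brain)

    ge_t = signal_to_delta_r2(ge_series, tumor)
    se_t = signal_to_delta_r2(se_series, tumor)
    fits_ge = fit_first_pass_many(ge_t.curves, ge_t.times)
    fits_se = fit_first_pass_many(se_t.curves, se_t.times)

    cbv_t = np.array([first_pass_area(f) for f in fits_ge]) / aif_ge.area
    ucbv_t = np.array([first_pass_area(f) for f in fits_se]) / aif_se.area
    cbf_t = compute_cbf(ge_t.curves, aif_ge, ge_series.frame_interval)

    # loop metrics from the fitted (smoothed) first-pass curves
    t_fine = np.linspace(ge_t.times[0], ge_t.times[-1], 4 * ge_t.times.size)
    ge_fit_curves = np.stack([f(t_fine) for f in fits_ge])
    se_fit_curves = np.stack([f(t_fine) for f in fits_se])
    mti_t = vam.mti_from_curves(ge_fit_curves, se_fit_curves)
    pk_ge = np.array([f.peak_value if f.valid else 0.0 for f in fits_ge])
    pk_se = np.array([f.peak_value if f.valid else 0.0 for f in fits_se])
    qmax_t = np.where(pk_se > 0, pk_ge / np.maximum(pk_se, 1e-30) ** 1.5, 0.0)

    def vol(tumor_vals):
        out = np.zeros(shape)
        out[tumor] = tumor_vals
        return out

    cbv = vol(cbv_t)
    cbf = vol(cbf_t)
    oxy = qbold.compute_oxygen_maps(r2s_map.rate.data, r2_map.rate.data, cbv, cbf, consts)
    adc = adc_map.data
    mvd_t, _ = vam.compute_mvd(qmax_t, cbv_t, adc[tumor])
    vsi_t, _ = vam.compute_vsi(cbv_t, adc[tumor], qmax_t)

    return {
        "maps": {
            "ceT1w": bundle.cet1w.data, "FLAIR": bundle.flair.data,
            "ADC": adc, "CBV": cbv,
            "OEF": np.where(tumor, oxy.oef, 0.0),
            "CMRO2": np.where(tumor, oxy.cmro2, 0.0),
            "capiPO2": np.where(tumor, oxy.capipo2, 0.0),
            "mitoPO2": np.where(tumor, oxy.mitopo2, 0.0),
            "uCBV": vol(ucbv_t), "MVD": vol(mvd_t), "VSI": vol(vsi_t), "MTI": vol(mti_t),
        },
        "brain_mask": brain, "tumor_mask": tumor,
        "voxel_size_mm": phantom.spec.voxel_size_mm,
        "parses": {"mvd": vam.MVD_PARSE, "vsi": vam.VSI_PARSE, "qmax": vam.QMAX_PARSE},
    }


def patient_feature_vectors(mapped: dict, policies: dict, maps_needed) -> dict:
    """107-feature vector per requested map of one mapped patient."""
    tumor = mapped["tumor_mask"]
    brain = mapped["brain_mask"]
    spacing = (mapped["voxel_size_mm"],) * 3
    out = {}
    for name in maps_needed:
        pol = policies[name]
        disc, rmask, values = preprocess_map(mapped["maps"][name], tumor, pol,
                                             spacing=spacing, norm_mask=brain)
        out[name] = extract_features(disc, rmask, spacing=(1.0,) * 3, values=values,
                                     source_map=name)
    return out


def cohort_feature_table(mapped_patients: list[dict], labels, categories,
                         policies: dict) -> dict[str, pd.DataFrame]:
    """Per-category feature table: rows = patients, columns = prefixed features."""
    maps_needed = sorted({m for c in categories for m in CATEGORY_MAPS[c]})
    per_patient = [patient_feature_vectors(mp, policies, maps_needed)
                   for mp in mapped_patients]
    tables = {}
    for cat in categories:
        rows = [assemble_vector(vecs, cat) for vecs in per_patient]
        df = pd.DataFrame([r.values for r in rows], columns=list(rows[0].names))
        df.insert(0, "label", list(labels))
        tables[cat] = df
    return tables


# ---------------------------------------------------------------------------
# experiment orchestration

@dataclass
class ExperimentConfig:
    """Cohort sizes, seeds, categories, models and protocol assignment."""

    n_train: int = 100
    n_test: int = 40
    n_external: int = 0
    seed: int = 1
    categories: tuple = ("oxymet",)
    models: tuple = ("RF",)
    train_protocol: str = "site_A_separate"
    external_protocol: str = "site_B_hybrid"
    grid_shape: tuple = (24, 24, 24)
    noise_sd: float = 0.003
    effect_scale: float = 1.0
    relieff_k: int = 10
    selection_fraction: float = 0.25
    wrapper_folds: int = 10
    wrapper_threshold: float = 0.01
    wrapper_candidate_cap: int | None = 15
    wrapper_max_features: int | None = 8
    smote_k: int = 5
    deep_hyper: dict = field(default_factory=dict)


@dataclass
class ExperimentResult:
    reports: list
    matrix: pd.DataFrame
    selections: dict
    models: dict
    tables: dict
    mti_limit: float


def _map_cohort(bundles):
    return [map_patient(b) for b in bundles]


def _train_one(kind: str, table: pd.DataFrame, cfg: ExperimentConfig, seed: int):
    """Feature selection (classical only), SMOTE, and model training."""
    y = table["label"].to_numpy()
    X = table.drop(columns="label").to_numpy()
    names = [c for c in table.columns if c != "label"]

    selection = None
    if kind in CLASSICAL_KINDS:
        _, ranking = relieff_rank(X, y, k_neighbors=cfg.relieff_k)
        shortlist = top_fraction(ranking, X.shape[1], cfg.selection_fraction)
        wrapped = lambda n_feats: make_classical_estimator(kind, n_feats, seed, {})
        selected, history = wrapper_select(
            list(shortlist), X, y, wrapped, folds=cfg.wrapper_folds,
            threshold=cfg.wrapper_threshold, seed=seed,
            max_features=cfg.wrapper_max_features,
            candidate_cap=cfg.wrapper_candidate_cap)
        if not selected:  # fall back to the best-ranked feature
            selected = [int(shortlist[0])]
        cols = selected
        selection = {"shortlist": [names[i] for i in shortlist],
                     "selected": [names[i] for i in selected],
                     "cv_history": history}
    else:
        cols = list(range(X.shape[1]))

    Xb, yb = smote_balance(X[:, cols], y, k=cfg.smote_k, seed=seed)
    feat_names = [names[i] for i in cols]
    spec = ModelSpec(kind, seed=seed, hyper=dict(cfg.deep_hyper))
    if kind in CLASSICAL_KINDS:
        model = train_classical(Xb, yb, spec, feature_names=feat_names)
    elif kind == "CNN1D":
        model = train_cnn1d(Xb, yb, spec, feature_names=feat_names)
    else:
        model = train_lstm(Xb, yb, spec, feature_names=feat_names)
    return model, cols, selection


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> ExperimentResult:
    """Run the full synthetic study and return per-model evaluation reports.

    Internal testing uses a held-out cohort under the training protocol;
    external testing (``n_external > 0``) uses the other site's protocol.
    Deterministic for a fixed config.
    """
    effects = default_class_effects(cfg.effect_scale)
    cohorts = {"train": simulate_cohort(cfg.n_train, effects, cfg.train_protocol,
                                        seed=2 * cfg.seed, grid_shape=cfg.grid_shape,
                                        noise_sd=cfg.noise_sd),
               "internal": simulate_cohort(cfg.n_test, effects, cfg.train_protocol,
                                           seed=2 * cfg.seed + 1, grid_shape=cfg.grid_shape,
                                           noise_sd=cfg.noise_sd)}
    if cfg.n_external > 0:
        cohorts["external"] = simulate_cohort(cfg.n_external, effects, cfg.external_protocol,
                                              seed=2 * cfg.seed + 2,
                                              grid_shape=cfg.grid_shape,
                                              noise_sd=cfg.noise_sd)
    labels = {k: [b.label for b in v] for k, v in cohorts.items()}
    mapped = {k: _map_cohort(v) for k, v in cohorts.items()}

    # MTI discretization range: symmetric, from the training cohort
    mti_vals = np.concatenate([mp["maps"]["MTI"][mp["tumor_mask"]]
                               for mp in mapped["train"]])
    mti_limit = max(float(np.percentile(np.abs(mti_vals), 99)), 1e-3)
    policies = default_biomarker_policies(mti_limit)

    tables = {k: cohort_feature_table(mapped[k], labels[k], cfg.categories, policies)
              for k in cohorts}

    reports, selections, models = [], {}, {}
    for cat in cfg.categories:
        for kind in cfg.models:
            model, cols, sel = _train_one(kind, tables["train"][cat], cfg, cfg.seed)
            selections[(kind, cat)] = sel
            models[(kind, cat)] = model
            for cohort_name in [k for k in cohorts if k != "train"]:
                tbl = tables[cohort_name][cat]
                Xt = tbl.drop(columns="label").to_numpy()[:, cols]
                p = model.predict_proba(Xt)
                reports.append(evaluate(p, np.asarray(labels[cohort_name]),
                                        model_id=kind, category=cat,
                                        cohort_id=cohort_name))
    # one matrix per test cohort
    by_cohort = {}
    for name in [k for k in cohorts if k != "train"]:
        by_cohort[name] = results_matrix([r for r in reports if r.cohort_id == name])
    matrix = pd.concat(by_cohort, names=["cohort"], axis=0) if by_cohort else pd.DataFrame()

    result = ExperimentResult(reports, matrix, selections, models, tables, mti_limit)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        matrix.to_csv(out / "results_matrix.csv")
        for k, t in tables.items():
            for cat, df in t.items():
                df.to_csv(out / f"features_{k}_{cat}.csv", index=False)
        prov = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(cfg).items()},
                "mti_limit": mti_limit,
                "parses": [vam.MVD_PARSE, vam.VSI_PARSE, vam.QMAX_PARSE]}
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    return result
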