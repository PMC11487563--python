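"""Orchestration: configuration, events I/O and the end-to-end analysis.

``run_pipeline`` ties every stage together on a synthetic cohort: voxelwise
prewhitened FIR GLMs, voxel selection, ROI eigenvariates, the four
HRF models (FIR32 basis GLM, canonical-plus-derivatives GLM, nonlinear
template fit, hemodynamic-model inversion), shape features with age
correlations, group PEB with Bayesian reduction of age effects, and
leave-one-out age prediction.  Everything is deterministic given the
cohort spec's seed; results come back as pandas tables in a
:class:`ResultsBundle`.

Events tables use the tab-separated BIDS events dialect (columns
``onset``, ``duration``, ``trial_type``; onsets in seconds).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import basis, cohort, features, glm, hdm, nlf, peb, vl
from .design import EventSequence

__all__ = [
    "RunConfig",
    "ResultsBundle",
    "read_events",
    "write_events",
    "run_pipeline",
]

KNOWN_MODELS = ("FIR32", "Can3", "NLF4", "HDM3")


@dataclass(frozen=True)
class RunConfig:
    """What to run and on which synthetic cohort."""

    cohort_spec: cohort.CohortSpec = field(default_factory=cohort.CohortSpec)
    models: tuple[str, ...] = KNOWN_MODELS
    rois: tuple[str, ...] | None = None  # None -> all ROIs in the spec
    fir_bins: int = 32
    fir_bin_width_s: float = 1.0
    bins_per_tr: int = 32
    voxel_alpha: float = 0.05
    run_peb: bool = True
    run_loo: bool = True
    vl_max_iter: int = 48

    def __post_init__(self):
        unknown = set(self.models) - set(KNOWN_MODELS)
        if unknown:
            raise ValueError(f"unknown model name(s): {sorted(unknown)}")
        if not self.models:
            raise ValueError("model list must be non-empty")


@dataclass(frozen=True)
class ResultsBundle:
    """Tables produced by one pipeline run (see ``run_pipeline``)."""

    fir_estimates: pd.DataFrame
    feature_table: pd.DataFrame
    age_correlations: pd.DataFrame
    group_effects: pd.DataFrame | None
    prediction_table: pd.DataFrame | None
    model_comparison: features.ModelComparison | None
    excluded_participants: tuple[int, ...]
    run_log: dict


# ---------------------------------------------------------------------------
# events I/O


def write_events(events: EventSequence, path) -> None:
    """Write a BIDS-style tab-separated events table."""
    df = pd.DataFrame({
        "onset": events.onsets,
        "duration": events.durations,
        "trial_type": events.trial_types,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path) -> EventSequence:
    """Read a tab-separated events table, validating schema and ordering."""
    if isinstance(path, io.IOBase):
        df = pd.read_csv(path, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"onset", "duration", "trial_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events table missing column(s): {sorted(missing)}")
    try:
        onsets = df["onset"].astype(float).to_numpy()
        durations = df["duration"].astype(float).to_numpy()
    except ValueError as err:
        for line, value in enumerate(df["onset"], start=2):
            try:
                float(value)
            except ValueError:
                raise ValueError(
                    f"non-numeric onset {value!r} at line {line}"
                ) from err
        raise
    bad = np.flatnonzero(np.diff(onsets) <= 0)
    if bad.size:
        raise ValueError(
            f"onsets not strictly increasing at line {int(bad[0]) + 3} "
            f"(onset {onsets[bad[0] + 1]} after {onsets[bad[0]]})"
        )
    return EventSequence(
        onsets=onsets,
        durations=durations,
        trial_types=df["trial_type"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# pipeline


def _first_level(config, dataset, roi_names):
    """Per participant/ROI: voxel GLM, selection, eigenvariate, FIR refit."""
    d = dataset.spec.design
    fir = basis.fir_basis(config.fir_bins, config.fir_bin_width_s,
                          d.tr_s / config.bins_per_tr)
    dct = glm.dct_highpass_set(d.n_scans, d.tr_s)
    fir_rows, eig = [], {}
    excluded = set()
    for i, part in enumerate(dataset.participants):
        X = basis.build_design_matrix(part.events, fir, d.tr_s, d.n_scans,
                                      config.bins_per_tr).matrix
        Xfull = np.column_stack([X, part.confounds, dct])
        for roi in roi_names:
            Y = part.voxel_data[roi]
            noise = glm.reml_ar1(Y - Y.mean(axis=0), Xfull)
            fit = glm.fit_glm(Y, X, confounds=part.confounds, noise=noise, dct=dct)
            sel = glm.participant_voxel_selection(fit, config.voxel_alpha)
            if sel.size == 0:
                excluded.add(i)
                continue
            # summarise confound-adjusted, whitened voxel data
            W = noise.whitener
            X0 = np.column_stack([part.confounds, dct])
            WY, WX0 = W @ Y, W @ X0
            adj = WY - WX0 @ np.linalg.lstsq(WX0, WY, rcond=None)[0]
            summary = glm.roi_eigenvariate(adj, sel)
            eig[(i, roi)] = (summary, noise)
            # FIR re-fit on the eigenvariate (already whitened and filtered)
            efit = glm.fit_glm(summary.eigenvariate, W @ X, grand_mean=None)
            fir_rows.append({"participant": i, "roi": roi, "age": part.age,
                             **{f"bin_{k:02d}": efit.coefficients[k]
                                for k in range(config.fir_bins)}})
    fir_df = pd.DataFrame(fir_rows)
    return fir_df, eig, excluded, fir, dct


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Run the full synthetic-cohort analysis (see module docstring)."""
    spec = config.cohort_spec
    dataset = cohort.generate_cohort(spec)
    d = spec.design
    roi_names = list(config.rois) if config.rois else list(spec.roi_profiles)
    unknown_rois = set(roi_names) - set(spec.roi_profiles)
    if unknown_rois:
        raise ValueError(f"config names unknown ROI(s): {sorted(unknown_rois)}")

    fir_df, eig, excluded, fir_set, dct = _first_level(config, dataset, roi_names)
    kept = [i for i in range(spec.n_participants) if i not in excluded]
    fir_df = fir_df[fir_df.participant.isin(kept)].reset_index(drop=True)
    ages = np.array([dataset.participants[i].age for i in kept])
    bin_cols = [c for c in fir_df.columns if c.startswith("bin_")]

    feature_rows = []
    loo_features: dict[str, list[np.ndarray]] = {m: [] for m in config.models}
    group_rows = []
    hdm_posteriors: dict[str, list[vl.Posterior]] = {}

    can3 = basis.informed_basis(step_s=d.tr_s / config.bins_per_tr)

    for roi in roi_names:
        roi_fir = fir_df[fir_df.roi == roi].set_index("participant")
        M = roi_fir.loc[kept, bin_cols].to_numpy()

        if "FIR32" in config.models:
            for row, i in zip(M, kept):
                f = features.peak_features(row, config.fir_bin_width_s)
                feature_rows.append(dict(model="FIR32", roi=roi, participant=i,
                                         amplitude=f.peak_amplitude,
                                         latency=f.peak_latency_s))
            loo_features["FIR32"].append(M)

        if "Can3" in config.models:
            betas = []
            for i in kept:
                summary, noise = eig[(i, roi)]
                X = basis.build_design_matrix(
                    dataset.participants[i].events, can3, d.tr_s, d.n_scans,
                    config.bins_per_tr).matrix
                cfit = glm.fit_glm(summary.eigenvariate, noise.whitener @ X,
                                   grand_mean=None)
                b = cfit.coefficients[:3]
                betas.append(b)
                curve = can3.columns @ b
                f = features.peak_features(curve, can3.step_s)
                feature_rows.append(dict(model="Can3", roi=roi, participant=i,
                                         amplitude=f.peak_amplitude,
                                         latency=f.peak_latency_s))
            loo_features["Can3"].append(np.array(betas))

        if "NLF4" in config.models:
            template = nlf.make_template(M, step_s=config.fir_bin_width_s,
                                         provenance=f"roi={roi}")
            rows = []
            for row, i in zip(M, kept):
                params, corr = nlf.fit_nlf(template, row)
                rows.append([params.a0, params.a1, params.t0, params.t1])
                feature_rows.append(dict(model="NLF4", roi=roi, participant=i,
                                         amplitude=params.a1,
                                         latency=abs(params.t1)))
            loo_features["NLF4"].append(np.array(rows))

        if "HDM3" in config.models:
            models = [vl.HDMModel(onsets=dataset.participants[i].events.onsets,
                                  tr_s=d.tr_s, n_scans=d.n_scans)
                      for i in kept]
            Y = np.stack([eig[(i, roi)][0].eigenvariate for i in kept])
            posts = vl.vl_fit_batch(Y, models, nuisance=dct,
                                    max_iter=config.vl_max_iter)
            hdm_posteriors[roi] = posts
            theta = np.array([p.mean for p in posts])
            loo_features["HDM3"].append(theta)
            # shape features from the fitted impulse response
            imp = [hdm.volterra_kernel1(models[0].params_from_theta(p.mean),
                                        np.arange(0, 24.1, hdm.DEFAULT_DT))
                   for p in posts]
            for i, p, k1 in zip(kept, posts, imp):
                f = features.peak_features(k1, hdm.DEFAULT_DT)
                rates = vl.posterior_rates_in_hz(p)
                feature_rows.append(dict(model="HDM3", roi=roi, participant=i,
                                         amplitude=f.peak_amplitude,
                                         latency=f.peak_latency_s,
                                         beta=rates.get("beta"),
                                         decay_hz=rates.get("kappa"),
                                         transit_hz=rates.get("transit_rate")))
            if config.run_peb and len(posts) >= 2:
                design = peb.GroupDesign.mean_and_age(ages)
                peb_res = peb.peb_fit(posts, design)
                search = peb.bmr_search(peb_res)
                for label, stats_ in search.retained.items():
                    pname, cname = label.split(":")
                    group_rows.append(dict(roi=roi, parameter=pname,
                                           covariate=cname, retained=True,
                                           **stats_))
                for label in search.pruned:
                    pname, cname = label.split(":")
                    group_rows.append(dict(roi=roi, parameter=pname,
                                           covariate=cname, retained=False,
                                           expectation=0.0,
                                           ci_low=0.0, ci_high=0.0))

    feature_df = pd.DataFrame(feature_rows)

    corr_rows = []
    for (model, roi), grp in feature_df.groupby(["model", "roi"]):
        grp = grp.sort_values("participant")
        for feat in ("amplitude", "latency"):
            try:
                rho, p = features.spearman_age(grp[feat].to_numpy(), ages)
            except ValueError:
                rho, p = np.nan, np.nan
            corr_rows.append(dict(model=model, roi=roi, feature=feat,
                                  spearman_rho=rho, p_value=p))
        if model == "HDM3":
            for feat in ("decay_hz", "transit_hz", "beta"):
                rho, p = features.spearman_age(grp[feat].to_numpy(), ages)
                corr_rows.append(dict(model=model, roi=roi, feature=feat,
                                      spearman_rho=rho, p_value=p))
    corr_df = pd.DataFrame(corr_rows)

    prediction_df, comparison = None, None
    if config.run_loo and len(kept) >= 8:
        model_feats = {}
        for m in config.models:
            F = np.hstack(loo_features[m])
            if F.shape[1] * 3 > len(kept) and m == "FIR32":
                # fall back to shape features when the full FIR parameter set
                # would leave the regression under-determined
                sub = feature_df[feature_df.model == "FIR32"].sort_values(
                    ["roi", "participant"])
                F = np.column_stack([
                    sub[sub.roi == roi][["amplitude", "latency"]].to_numpy()
                    for roi in roi_names
                ])
            if F.shape[1] + 1 < len(kept):
                model_feats[m] = F
        if model_feats:
            comparison = features.compare_models(model_feats, ages)
            pred_rows = []
            for m, err in comparison.absolute_errors.items():
                for i, e in zip(kept, err):
                    pred_rows.append(dict(model=m, participant=i,
                                          absolute_error=e))
            prediction_df = pd.DataFrame(pred_rows)

    group_df = pd.DataFrame(group_rows) if group_rows else None
    run_log = dict(
        seed=spec.seed,
        n_participants=spec.n_participants,
        models=list(config.models),
        rois=roi_names,
        excluded=sorted(excluded),
        tr_s=d.tr_s,
        n_scans=d.n_scans,
    )
    return ResultsBundle(
        fir_estimates=fir_df,
        feature_table=feature_df,
        age_correlations=corr_df,
        group_effects=group_df,
        prediction_table=prediction_df,
        model_comparison=comparison,
        excluded_participants=tuple(sorted(excluded)),
        run_log=run_log,
    )
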