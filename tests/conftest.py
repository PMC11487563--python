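"""Shared fixtures.

The expensive fixtures (a 200-participant cohort taken through the full
first-level + hemodynamic-inversion path, and a batch of noisy inversion
replicates) are session-scoped so the group-level and end-to-end tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from boldhrf import basis, cohort, glm, vl


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def _roi_eigenvariates(dataset, roi: str):
    """First-level path for one ROI: voxel GLM, selection, eigenvariate."""
    d = dataset.spec.design
    fir = basis.fir_basis(microtime_step_s=d.tr_s / 32)
    dct = glm.dct_highpass_set(d.n_scans, d.tr_s)
    eigs, kept = [], []
    for i, part in enumerate(dataset.participants):
        X = basis.build_design_matrix(part.events, fir, d.tr_s, d.n_scans).matrix
        Xfull = np.column_stack([X, part.confounds, dct])
        Y = part.voxel_data[roi]
        noise = glm.reml_ar1(Y - Y.mean(axis=0), Xfull)
        fit = glm.fit_glm(Y, X, confounds=part.confounds, noise=noise, dct=dct)
        sel = glm.participant_voxel_selection(fit)
        if sel.size == 0:
            continue
        W = noise.whitener
        X0 = np.column_stack([part.confounds, dct])
        WY, WX0 = W @ Y, W @ X0
        adj = WY - WX0 @ np.linalg.lstsq(WX0, WY, rcond=None)[0]
        eigs.append(glm.roi_eigenvariate(adj, sel).eigenvariate)
        kept.append(i)
    return np.stack(eigs), kept, dct


@pytest.fixture(scope="session")
def cohort200_hdm_fits():
    """n = 200 single-ROI cohort with the default age trends, taken through
    voxel GLMs, eigenvariate extraction and hemodynamic-model inversion.

    Returns (dataset, kept_indices, ages, posteriors).
    """
    spec = cohort.CohortSpec(
        n_participants=200,
        seed=2026,
        roi_profiles={"auditory": cohort.ROIProfile(n_voxels=12)},
    )
    dataset = cohort.generate_cohort(spec)
    Y, kept, dct = _roi_eigenvariates(dataset, "auditory")
    d = spec.design
    models = [
        vl.HDMModel(onsets=dataset.participants[i].events.onsets,
                    tr_s=d.tr_s, n_scans=d.n_scans)
        for i in kept
    ]
    posteriors = vl.vl_fit_batch(Y, models, nuisance=dct)
    ages = np.array([dataset.participants[i].age for i in kept])
    return dataset, kept, ages, posteriors


@pytest.fixture(scope="session")
def cohort120_direct_fits():
    """n = 120 cohort with the default age trends, single-voxel ROIs read
    out directly (no eigenvariate step), inverted participant by
    participant.  Isolates hierarchical group inference from ROI
    summarisation artefacts."""
    spec = cohort.CohortSpec(
        n_participants=120,
        seed=2026,
        roi_profiles={"auditory": cohort.ROIProfile(
            n_voxels=1, shared_signal_fraction=1.0, voxel_noise_sd=0.0)},
        noise=cohort.NoiseSpec(innovation_sd=0.3, drift_amplitude=0.0,
                               confound_leakage=0.0),
    )
    dataset = cohort.generate_cohort(spec)
    d = spec.design
    models, Y = [], []
    for part in dataset.participants:
        models.append(vl.HDMModel(onsets=part.events.onsets,
                                  tr_s=d.tr_s, n_scans=d.n_scans))
        Y.append(part.voxel_data["auditory"][:, 0] - 100.0)
    posteriors = vl.vl_fit_batch(np.stack(Y), models)
    return dataset, posteriors


@pytest.fixture(scope="session")
def short_design_model():
    """A compact event design (degree-6 m-sequence, 126 s run) used for
    inversion replicates where the full-length run would be wasteful."""
    from boldhrf import design

    seq = design.generate_msequence(6)
    ev = design.build_event_timing(seq, rng=np.random.default_rng(7))
    return vl.HDMModel(onsets=ev.onsets, tr_s=2.0, n_scans=64)
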