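"""First-level GLM: design assembly, OLS recovery, scrubbing, concatenation."""

import numpy as np
import pytest

from rlbold import (
    EffectMap,
    NoiseConfig,
    ROIEffect,
    TaskConfig,
    build_design,
    concatenate_sessions,
    fit_glm,
    generate_schedule,
    simulate_bold,
    subject_contrast,
)
from rlbold.bold_sim import NuisanceTable, VolumeSeries
from rlbold.glm import DesignError


@pytest.fixture(scope="module")
def run():
    sch = generate_schedule(TaskConfig(seed=51), 1)
    rng = np.random.default_rng(1)
    dv = rng.uniform(-1, 1, size=len(sch))
    return sch, dv


def _n_volumes(sch, tr=2.5):
    return int(np.ceil((sch.trials[-1].onset + 20.0) / tr))


def test_design_has_task_and_modulator_columns(run):
    sch, dv = run
    design = build_design(sch, dv_series=dv)
    assert design.columns[:2] == ["task_onsets", "dv_modulator"]
    assert "intercept" in design.columns
    # modulator is mean-centered before stick weighting: orthogonal in weight
    assert abs((dv - dv.mean()).sum()) < 1e-9


def test_constant_dv_modulator_flagged_as_zero(run):
    sch, _ = run
    design = build_design(sch, dv_series=np.full(len(sch), 0.7))
    assert np.allclose(design.frame["dv_modulator"], 0.0)
    assert any("zero" in f for f in design.flags)


def test_orthogonalized_modulator_is_orthogonal(run):
    sch, dv = run
    design = build_design(sch, dv_series=dv, orthogonalize_modulator=True)
    task = design.frame["task_onsets"].to_numpy()
    mod = design.frame["dv_modulator"].to_numpy()
    assert abs(task @ mod) < 1e-8


def test_fd_spike_columns_one_per_censored_volume(run):
    sch, dv = run
    n_vol = _n_volumes(sch)
    rng = np.random.default_rng(9)
    motion = np.cumsum(rng.normal(0, 0.002, size=(n_vol, 6)), axis=0)
    motion[5:, 0] += 0.25  # one super-threshold 0.25 mm jump at volume 5
    nuis = NuisanceTable(rng.normal(size=n_vol), rng.normal(size=n_vol), motion)
    design = build_design(sch, dv_series=dv, nuisance=nuis)
    spikes = design.groups["spikes"]
    assert spikes == ["fd_spike_5"]
    col = design.frame["fd_spike_5"].to_numpy()
    assert col[5] == 1.0 and col.sum() == 1.0
    # nuisance block is complete: 2 signals + 6 motion + 6 derivatives
    assert len(design.groups["nuisance"]) == 14


def test_condition_mode_one_regressor_per_outcome_class(run):
    sch, _ = run
    labels = ["Hit", "CR"] * (len(sch) // 2)
    design = build_design(sch, condition_labels=labels, mode="condition_events")
    assert sorted(design.groups["task"]) == ["cond_CR", "cond_Hit"]


def test_rank_deficiency_reported_with_columns(run):
    sch, dv = run
    n_vol = _n_volumes(sch)
    # duplicated motion columns are perfectly collinear
    motion = np.tile(np.linspace(0, 0.1, n_vol)[:, None], (1, 6))
    nuis = NuisanceTable(np.zeros(n_vol), np.zeros(n_vol), motion)
    with pytest.raises(DesignError, match="collinear"):
        build_design(sch, dv_series=dv, nuisance=nuis)


def test_ols_recovers_known_coefficients_exactly(run):
    """Data built as design x known betas is inverted to 1e-8."""
    sch, dv = run
    design = build_design(sch, dv_series=dv)
    X = design.matrix
    rng = np.random.default_rng(2)
    true_beta = rng.normal(size=(X.shape[1], 4))
    Y = X @ true_beta  # four noiseless voxels
    data = Y.T.reshape(2, 2, 1, X.shape[0])
    vol = VolumeSeries(data=data)
    result = fit_glm(vol, design)
    for j, name in enumerate(design.columns):
        est = result.coefficients[name].ravel()
        assert np.allclose(est, true_beta[j], atol=1e-8)
    assert np.allclose(result.residual_variance, 0.0, atol=1e-12)


def test_end_to_end_noiseless_amplitude_recovery(run):
    """The planted decision-variable amplitude is read back from the
    dv_modulator coefficient to machine precision."""
    sch, dv = run
    effects = EffectMap(
        {"pos": ROIEffect([[1, 1, 0]], 1.7), "neg": ROIEffect([[3, 2, 1]], -0.9)}
    )
    vol, nuis, truth = simulate_bold(
        sch, dv, effects, shape=(6, 6, 2),
        noise=NoiseConfig(sigma=0.0, ar_coef=0.0), seed=3,
    )
    design = build_design(
        sch, dv_series=dv, nuisance=nuis, n_volumes=vol.n_volumes
    )
    result = fit_glm(vol, design)
    cmap = subject_contrast(result, "dv_modulator")
    assert cmap.data[1, 1, 0] == pytest.approx(1.7, rel=1e-6)
    assert cmap.data[3, 2, 1] == pytest.approx(-0.9, rel=1e-6)
    assert cmap.data[0, 0, 0] == pytest.approx(0.0, abs=1e-8)


def test_contrast_vector_interface(run):
    sch, dv = run
    design = build_design(sch, dv_series=dv)
    X = design.matrix
    vol = VolumeSeries(data=np.ones((2, 1, 1, X.shape[0])))
    result = fit_glm(vol, design)
    k = len(design.columns)
    ident = np.zeros(k)
    ident[0] = 1.0
    m1 = subject_contrast(result, ident)
    assert np.allclose(m1.data, result.coefficients["task_onsets"])
    assert np.all(subject_contrast(result, np.zeros(k)).data == 0.0)
    two = np.zeros(k)
    two[0], two[1] = 1.0, -1.0
    m2 = subject_contrast(result, two)
    diff = result.coefficients["task_onsets"] - result.coefficients["dv_modulator"]
    assert np.allclose(m2.data, diff)
    with pytest.raises(ValueError):
        subject_contrast(result, np.zeros(k + 1))


def test_spike_column_equals_volume_deletion(run):
    """OLS with a one-hot spike regressor reproduces the coefficients from
    simply deleting the censored volume."""
    sch, dv = run
    design = build_design(sch, dv_series=dv)
    X = design.matrix
    n_vol = X.shape[0]
    rng = np.random.default_rng(4)
    y = X @ rng.normal(size=X.shape[1]) + rng.normal(size=n_vol)
    censor = 7
    spike = np.zeros((n_vol, 1))
    spike[censor] = 1.0
    Xs = np.hstack([X, spike])
    beta_spike, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    keep = np.arange(n_vol) != censor
    beta_del, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
    assert np.allclose(beta_spike[: X.shape[1]], beta_del, atol=1e-8)


def test_concatenate_sessions_run_constants(run):
    sch, dv = run
    d1 = build_design(sch, dv_series=dv)
    d2 = build_design(sch, dv_series=dv)
    n_vol = d1.n_volumes
    data = np.random.default_rng(5).normal(size=(2, 2, 1, n_vol))
    v1 = VolumeSeries(data=data)
    v2 = VolumeSeries(data=data + 1.0)
    stacked_vol, stacked_design = concatenate_sessions([v1, v2], [d1, d2])
    assert stacked_vol.n_volumes == 2 * n_vol
    assert stacked_design.groups["run_constants"] == ["run_const_0"]
    const = stacked_design.frame["run_const_0"].to_numpy()
    assert const[:n_vol].all() and not const[n_vol:].any()
    # single run: no run constants
    _, single = concatenate_sessions([v1], [d1])
    assert single.groups["run_constants"] == []


def test_concatenated_fit_equals_hand_built_design(run):
    sch, dv = run
    d1 = build_design(sch, dv_series=dv)
    n_vol = d1.n_volumes
    rng = np.random.default_rng(6)
    data1 = rng.normal(size=(1, 1, 1, n_vol))
    data2 = rng.normal(size=(1, 1, 1, n_vol))
    v1, v2 = VolumeSeries(data=data1), VolumeSeries(data=data2)
    stacked_vol, stacked_design = concatenate_sessions([v1, v2], [d1, d1])
    result = fit_glm(stacked_vol, stacked_design)
    # hand-built equivalent
    X1 = d1.frame.drop(columns="intercept").to_numpy()
    Xc = np.vstack([X1, X1])
    run_const = np.concatenate([np.ones(n_vol), np.zeros(n_vol)])
    Xfull = np.column_stack([Xc, run_const, np.ones(2 * n_vol)])
    y = np.concatenate([data1.ravel(), data2.ravel()])
    beta, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    shared = [c for c in stacked_design.columns
              if c not in ("run_const_0", "intercept")]
    for j, name in enumerate(shared):
        assert result.coefficients[name].ravel()[0] == pytest.approx(
            beta[j], abs=1e-8
        )


def test_grid_mismatch_rejected(run):
    sch, dv = run
    d = build_design(sch, dv_series=dv)
    n_vol = d.n_volumes
    v1 = VolumeSeries(data=np.zeros((2, 2, 1, n_vol)))
    v2 = VolumeSeries(data=np.zeros((3, 2, 1, n_vol)))
    with pytest.raises(ValueError, match="grid"):
        concatenate_sessions([v1, v2], [d, d])
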