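"""Encoding-model pipeline: covariate conventions, inclusion rule,
penalized Poisson fits, DIC selection, Shapley axioms and tuning curves."""

import itertools
import math

import numpy as np
import pytest

from batcolony import encoding as enc
from batcolony.errors import ConfigError
from batcolony.session_io import SpikeTrain

from conftest import encoding_run, make_static_session


# ---------------------------------------------------------------------------
# covariate conventions
# ---------------------------------------------------------------------------


def _conv_session(host_hd, target_offset):
    """Host at the large-net centre plus three padding conspecifics; the
    probe target sits at ``target_offset`` from the host."""
    host = np.array([0.4, 0.2, 2.4])
    pts = {
        "H": host,
        "T": host + np.array([*target_offset, 0.0]),
        "P1": host + np.array([0.25, 0.1, 0.0]),
        "P2": host + np.array([-0.25, 0.1, 0.0]),
        "P3": host + np.array([0.3, -0.1, 0.0]),
    }
    return make_static_session(
        pts, n_frames=50, head_dir={"H": host_hd}, frame_rate=10.0
    )


@pytest.mark.parametrize(
    "host_hd,offset,want_theta",
    [
        (0.0, (0.2, 0.0), 0.0),  # facing +x, target ahead
        (0.0, (0.0, 0.2), 90.0),  # target to the left
        (90.0, (0.2, 0.0), -90.0),  # facing +y, target to the right
        (180.0, (0.2, 0.0), 180.0 - 360.0),  # directly behind -> -180
    ],
)
def test_egocentric_angle_convention(host_hd, offset, want_theta):
    traj = _conv_session(host_hd, offset)
    frame = enc.build_covariates(traj, "H")
    j = frame.conspecifics.index("T")
    assert frame.theta[0, j] == pytest.approx(want_theta, abs=1e-9)
    assert frame.dist[0, j] == pytest.approx(np.hypot(*offset), abs=1e-9)


def test_bins_require_three_conspecifics():
    host = np.array([0.4, 0.2, 2.4])
    traj = make_static_session(
        {"H": host, "T": host + [0.2, 0, 0], "U": host + [0.1, 0.1, 0]},
        n_frames=20,
        head_dir={"H": 0.0},
        frame_rate=10.0,
    )
    with pytest.raises(Exception):
        enc.build_covariates(traj, "H")


# ---------------------------------------------------------------------------
# inclusion rule
# ---------------------------------------------------------------------------


def _frame_with_duration(seconds, bin_width=0.5):
    n = int(round(seconds / bin_width))
    m = 3
    rng = np.random.default_rng(0)
    return enc.CovariateFrame(
        host="H",
        conspecifics=["A", "B", "C"],
        bin_width=bin_width,
        bin_start_times=np.arange(n) * bin_width,
        host_pos=rng.uniform(0, 0.4, (n, 2)),
        host_hd=rng.uniform(0, 360, n),
        theta=rng.uniform(-180, 180, (n, m)),
        dist=rng.uniform(0.05, 0.8, (n, m)),
        allo=rng.uniform(0, 0.4, (n, m, 2)),
        present=np.ones((n, m), dtype=bool),
        net_diagonal=math.hypot(0.8, 0.4),
    )


def _spikes(n, t_max):
    return SpikeTrain("u", "H", np.linspace(0.0, t_max * 0.999, n))


@pytest.mark.parametrize(
    "seconds,n_spikes,included",
    [
        (599.0, 500, False),  # too little qualifying time
        (1200.0, 99, False),  # too few spikes
        (600.0, 100, True),  # both thresholds met exactly (closed bounds)
    ],
)
def test_inclusion_filter_boundaries(seconds, n_spikes, included):
    frame = _frame_with_duration(seconds)
    ok, summary = enc.inclusion_filter(_spikes(n_spikes, seconds), frame)
    assert ok is included
    assert summary["qualifying_spikes"] == n_spikes


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def test_intercept_only_fit_recovers_mean_rate():
    frame = _frame_with_duration(600.0)
    rng = np.random.default_rng(3)
    counts = rng.poisson(1.5, frame.n_bins).astype(float)
    fit = enc.fit_encoding_model(frame, (), counts)
    rate = math.exp(fit.beta[0])  # Hz; offset = log(bin width)
    assert rate * frame.bin_width == pytest.approx(counts.mean(), rel=0.05)


def test_tuned_variable_explains_more_deviance_than_untuned():
    frame, counts, spec = encoding_run("egocentric", seed=31, duration=1200)
    builder = enc.DesignBuilder(frame, enc.BasisConfig())
    dev_b = enc.fit_encoding_model(
        frame, [("angle", "B"), ("dist", "B")], counts, builder=builder
    ).deviance
    dev_c = enc.fit_encoding_model(
        frame, [("angle", "C"), ("dist", "C")], counts, builder=builder
    ).deviance
    assert dev_b < dev_c


def test_noise_variable_barely_changes_explained_deviance():
    """With ridge shrinkage, adding an untuned conspecific's variables moves
    the explained deviance by well under 2% of the baseline deviance."""
    frame, counts, _ = encoding_run("egocentric", seed=32, duration=1200)
    builder = enc.DesignBuilder(frame, enc.BasisConfig())
    base = enc.fit_encoding_model(frame, (), counts, builder=builder).deviance
    tuned = enc.fit_encoding_model(
        frame, [("angle", "B"), ("dist", "B")], counts, builder=builder
    ).deviance
    plus_noise = enc.fit_encoding_model(
        frame,
        [("angle", "B"), ("dist", "B"), ("angle", "C"), ("dist", "C")],
        counts,
        builder=builder,
    ).deviance
    assert abs(tuned - plus_noise) / base < 0.02


def test_nested_penalized_deviance_monotone():
    frame, counts, _ = encoding_run("egocentric", seed=33, duration=900)
    builder = enc.DesignBuilder(frame, enc.BasisConfig())
    base = enc.fit_encoding_model(frame, (), counts, builder=builder).deviance
    one = enc.fit_encoding_model(frame, [("angle", "B")], counts, builder=builder).deviance
    assert one <= base + 1e-6


def test_duplicating_data_doubles_deviance_keeps_class():
    frame, counts, _ = encoding_run("egocentric", seed=34, duration=900)
    cls1 = enc.classify_neuron(frame, counts)
    frame2 = enc.CovariateFrame(
        host=frame.host,
        conspecifics=frame.conspecifics,
        bin_width=frame.bin_width,
        bin_start_times=np.concatenate(
            [frame.bin_start_times, frame.bin_start_times + 1e6]
        ),
        host_pos=np.vstack([frame.host_pos] * 2),
        host_hd=np.concatenate([frame.host_hd] * 2),
        theta=np.vstack([frame.theta] * 2),
        dist=np.vstack([frame.dist] * 2),
        allo=np.vstack([frame.allo] * 2),
        present=np.vstack([frame.present] * 2),
        net_diagonal=frame.net_diagonal,
    )
    cls2 = enc.classify_neuron(frame2, np.concatenate([counts] * 2))
    assert cls1.label == cls2.label == enc.CLASS_EGO
    assert cls2.fit_ego.deviance == pytest.approx(
        2 * cls1.fit_ego.deviance, rel=0.02
    )


def test_dic_margin_is_strict():
    assert enc.dic_label(10.0) == enc.CLASS_NONE
    assert enc.dic_label(-10.0) == enc.CLASS_NONE
    assert enc.dic_label(10.001) == enc.CLASS_EGO
    assert enc.dic_label(-10.001) == enc.CLASS_ALLO


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------


def _shapley_by_permutations(values, n):
    """Independent oracle: average marginal contribution over all n!
    orderings."""
    phi = np.zeros(n)
    for perm in itertools.permutations(range(n)):
        mask = 0
        for i in perm:
            before = values[mask]
            mask |= 1 << i
            phi[i] += values[mask] - before
    return phi / math.factorial(n)


class TestShapley:
    def test_toy_two_variable_case(self):
        v = {0b00: 0.0, 0b01: 0.3, 0b10: 0.1, 0b11: 0.4}
        phi = enc.shapley_from_values(v, 2)
        np.testing.assert_allclose(phi, [0.3, 0.1], atol=1e-15)
        np.testing.assert_allclose(phi, _shapley_by_permutations(v, 2), atol=1e-15)

    def test_matches_permutation_oracle_on_random_games(self):
        rng = np.random.default_rng(8)
        for n in (3, 4, 5):
            v = {0: 0.0}
            for mask in range(1, 1 << n):
                v[mask] = float(rng.uniform(0, 1))
            np.testing.assert_allclose(
                enc.shapley_from_values(v, n),
                _shapley_by_permutations(v, n),
                atol=1e-12,
            )

    def test_dummy_variable_gets_zero(self):
        rng = np.random.default_rng(9)
        n = 4
        v = {0: 0.0}
        for mask in range(1, 1 << n):
            v[mask] = float(rng.uniform(0, 1))
        # make variable 3 a dummy: v(S + {3}) = v(S)
        for mask in range(1 << n):
            if mask & 0b1000:
                v[mask] = v[mask & 0b0111]
        phi = enc.shapley_from_values(v, n)
        assert abs(phi[3]) < 1e-12

    def test_symmetric_variables_get_equal_phi(self):
        # v depends only on |S| -> all variables exchangeable
        n = 4
        v = {mask: math.sqrt(bin(mask).count("1")) for mask in range(1 << n)}
        phi = enc.shapley_from_values(v, n)
        np.testing.assert_allclose(phi, phi[0], atol=1e-12)

    def test_attribution_targets_generative_bat(self):
        frame, counts, spec = encoding_run("egocentric", seed=35)
        attr = enc.shapley_attribution(frame, counts)
        assert attr.top_angle_bat == spec.target
        assert attr.phi.sum() == pytest.approx(attr.v_full, abs=1e-9)

    def test_variable_cap_enforced(self):
        frame = _frame_with_duration(600.0)
        frame.conspecifics = [f"b{i}" for i in range(8)]  # 16 variables
        frame.present = np.ones((frame.n_bins, 8), dtype=bool)
        with pytest.raises(ConfigError):
            enc.shapley_attribution(frame, np.zeros(frame.n_bins))


# ---------------------------------------------------------------------------
# tuning curves and population report
# ---------------------------------------------------------------------------


def test_tuning_curve_peak_matches_generative_angle():
    frame, counts, spec = encoding_run("egocentric", seed=36)
    tc = enc.tuning_curve(frame, counts, spec.target, "angle")
    assert tc.bin_edges[0] == -180.0 and tc.bin_edges[-1] == 180.0
    # generative preferred angle 45 deg lies at a bin centre
    assert tc.preferred == pytest.approx(45.0)
    assert np.all(tc.rates[~np.isnan(tc.rates)] >= 0)


def test_delta_elo_classes():
    assert enc.delta_elo_class(-51.0) == "lower"
    assert enc.delta_elo_class(-50.0) == "similar"
    assert enc.delta_elo_class(50.0) == "similar"
    assert enc.delta_elo_class(50.1) == "higher"


def test_population_report_degenerate_front():
    """A cohort whose neurons all prefer 15 deg: Kuiper rejects uniformity
    and every top bat is in front."""
    import pandas as pd

    from batcolony.dominance import EloState

    elo = EloState(
        {"H": 1000.0, "B": 1100.0, "C": 900.0, "D": 1000.0}, 32.0, pd.DataFrame()
    )
    sexes = {"H": "female", "B": "male", "C": "female", "D": "male"}
    summaries = [
        enc.NeuronSummary(
            f"u{i}", "H", enc.CLASS_EGO, 50.0,
            top_angle_bat="B", top_distance_bat="C",
            phi_angle=0.2, phi_distance=0.05,
            preferred_angle=15.0, preferred_distance=0.3,
        )
        for i in range(8)
    ]
    rep = enc.tuning_and_population(summaries, elo, sexes)
    assert rep["n_egocentric"] == 8
    assert rep["front_fraction"] == 1.0
    assert rep["angle_kuiper"].p_value < 0.01
    assert rep["delta_elo_hist_angle"] == {"lower": 0, "similar": 0, "higher": 8}
    assert rep["delta_elo_chi2_angle"].df == 2
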