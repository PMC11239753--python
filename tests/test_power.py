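import numpy as np
import pytest
from scipy import stats

from mliswd import (
    ContrastSpec,
    CorrelationSpec,
    MeanModelSpec,
    MultiplicityPlan,
    SingularInformationError,
    VarianceSpec,
    make_standard_swd,
    model_covariance,
    multi_test_power,
    wald_power,
)
from _oracle import oracle_model_covariance
from conftest import random_instance


def gaussian_specs(theta, T, scaling=(2.0, 2.0, 2.0), phi=1.0, alpha=(0.05, 0.025, 0.5)):
    mspec = MeanModelSpec(
        "incremental", "linear", "identity", theta, scaling=scaling, n_periods=T
    )
    return mspec, CorrelationSpec("block_exchangeable", alpha), VarianceSpec("gaussian", phi)


class TestModelCovariance:
    def test_hand_assembled_information(self):
        """Two-sequence AIM design small enough to write the information
        matrix down by hand."""
        layout = make_standard_swd(3, 2, 1, 2, 0.5)
        mspec = MeanModelSpec(
            "average", "linear", "identity", (0.0,) * 5, n_periods=3
        )
        cspec = CorrelationSpec("independence")
        vspec = VarianceSpec("gaussian", 1.0)
        omega = model_covariance(layout, mspec, cspec, vspec)

        def rows(crossover):
            out = []
            for treated in (0, 1):
                for j in (1, 2, 3):
                    cl = float(j >= crossover)
                    out.append([1, j, float(treated), cl, float(treated) * cl])
            return out

        X1, X2 = np.array(rows(2)), np.array(rows(3))
        assert np.allclose(omega, np.linalg.inv(X1.T @ X1 + X2.T @ X2))

    def test_ols_limit_independence_unit_dispersion(self):
        """With R = I and phi = 1 the model-based covariance is the OLS
        (X'X)^-1 summed over clusters."""
        layout = make_standard_swd(4, 3, 2, 3, 0.5)
        mspec, _, vspec = gaussian_specs((0.0,) * 5, 4)
        cspec = CorrelationSpec("independence")
        omega = model_covariance(layout, mspec, cspec, vspec)
        from mliswd import build_cluster_design

        info = sum(
            build_cluster_design(layout, mspec, i).T @ build_cluster_design(layout, mspec, i)
            for i in range(layout.n_clusters)
        )
        assert np.allclose(omega, np.linalg.inv(info), rtol=1e-12)

    @pytest.mark.parametrize("seed", range(24))
    def test_matches_dense_blockdiagonal_oracle(self, seed):
        """Structured per-cluster assembly equals a from-scratch dense
        block-diagonal construction on random small instances (all links)."""
        layout, mspec, cspec, vspec = random_instance(np.random.default_rng(1000 + seed))
        omega = model_covariance(layout, mspec, cspec, vspec)
        dense = oracle_model_covariance(layout, mspec, cspec, vspec)
        scale = np.abs(dense).max()
        assert np.allclose(omega, dense, rtol=1e-8, atol=1e-12 * scale)

    def test_singular_information_names_columns(self):
        # a single sequence crossing at the last period with one cluster and
        # an interaction that is never doubly exposed for long enough to be
        # separated: force degeneracy with il_split=1 (no IL-control arm, so
        # the IL column is proportional to the time column)
        layout = make_standard_swd(3, 1, 1, 2, 1.0)
        mspec, cspec, vspec = gaussian_specs((0.0,) * 5, 3)
        with pytest.raises(SingularInformationError, match="il"):
            model_covariance(layout, mspec, cspec, vspec)

    def test_dispersion_scale_equivariance(self):
        """Identity link: multiplying phi by k multiplies Omega by k and
        divides every noncentrality by k."""
        layout = make_standard_swd(4, 3, 2, 4, 0.5)
        theta = (0.0, 0.1, 0.2, 0.3, -0.1)
        contrast = ContrastSpec.single(3, 5, alpha=0.05)
        m1, c1, v1 = gaussian_specs(theta, 4, phi=1.0)
        m4, c4, v4 = gaussian_specs(theta, 4, phi=4.0)
        om1 = model_covariance(layout, m1, c1, v1)
        om4 = model_covariance(layout, m4, c4, v4)
        assert np.allclose(om4, 4.0 * om1, rtol=1e-12)
        r1 = wald_power(om1, theta, contrast, layout.n_clusters, "chisq")
        r4 = wald_power(om4, theta, contrast, layout.n_clusters, "chisq")
        assert r4.noncentrality == pytest.approx(r1.noncentrality / 4.0, rel=1e-12)


class TestWaldPower:
    def test_null_configuration_gives_alpha(self):
        omega = np.eye(3) * 0.01
        theta = (0.0, 0.0, 0.0)
        contrast = ContrastSpec.single(2, 3, alpha=0.05)
        res = wald_power(omega, theta, contrast, n_clusters=30, method="chisq")
        assert res.noncentrality == 0.0
        assert res.power == pytest.approx(0.05, abs=1e-12)

    def test_classic_calibration_point(self):
        """lambda = 7.849 at alpha = 0.05 with one degree of freedom is the
        textbook 80%-power configuration."""
        # choose omega so that (L theta)' (L omega L')^-1 (L theta) = 7.849
        lam = 7.849
        omega = np.array([[1.0 / lam]])
        contrast = ContrastSpec(L=((1.0,),), ell=(0.0,), alpha=0.05)
        res = wald_power(omega, (1.0,), contrast, n_clusters=100, method="chisq")
        assert res.noncentrality == pytest.approx(lam)
        assert res.power == pytest.approx(0.80, abs=5e-4)

    def test_chisq_dominates_small_sample_f(self):
        omega = np.array([[0.02]])
        contrast = ContrastSpec(L=((1.0,),), ell=(0.0,), alpha=0.05)
        for I in (8, 20, 50):
            chi = wald_power(omega, (0.3,), contrast, I, "chisq").power
            f = wald_power(omega, (0.3,), contrast, I, "f_small_sample").power
            assert chi >= f

    def test_chisq_and_f_converge_with_many_clusters(self):
        omega = np.array([[0.02]])
        contrast = ContrastSpec(L=((1.0,),), ell=(0.0,), alpha=0.05)
        chi = wald_power(omega, (0.3,), contrast, 1001, "chisq").power
        f = wald_power(omega, (0.3,), contrast, 1001, "f_small_sample").power
        assert abs(chi - f) < 2e-3

    def test_power_monotone_in_effect_size(self):
        omega = np.eye(2) * 0.01
        contrast = ContrastSpec.single(1, 2, alpha=0.05)
        powers = [
            wald_power(omega, (0.0, e), contrast, 40, "chisq").power
            for e in np.linspace(0.0, 0.5, 8)
        ]
        assert (np.diff(powers) >= 0).all()

    def test_joint_contrast_q2(self):
        omega = np.eye(3) * 0.01
        L = ((0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
        contrast = ContrastSpec(L=L, ell=(0.0, 0.0), alpha=0.05)
        res = wald_power(omega, (0.0, 0.2, 0.2), contrast, 30, "chisq")
        assert res.q == 2
        lam = 0.2 ** 2 / 0.01 * 2
        assert res.noncentrality == pytest.approx(lam)
        assert res.power == pytest.approx(stats.ncx2.sf(stats.chi2.ppf(0.95, 2), 2, lam))

    def test_nonzero_null_vector(self):
        omega = np.array([[0.01]])
        contrast = ContrastSpec(L=((1.0,),), ell=(0.25,), alpha=0.05)
        res = wald_power(omega, (0.25,), contrast, 30, "chisq")
        assert res.power == pytest.approx(0.05)

    def test_f_needs_positive_denominator_df(self):
        omega = np.eye(5) * 0.01
        contrast = ContrastSpec.single(0, 5, alpha=0.05)
        with pytest.raises(ValueError, match="I - d"):
            wald_power(omega, (0.3,) * 5, contrast, n_clusters=5, method="f_small_sample")

    def test_rank_deficient_contrast_rejected(self):
        with pytest.raises(ValueError):
            ContrastSpec(L=((1.0, 0.0), (2.0, 0.0)), ell=(0.0, 0.0), alpha=0.05)


class TestMultiplicity:
    def test_single_test_matches_wald_power(self, small_layout):
        mspec, cspec, vspec = gaussian_specs((0.0, 0.1, 0.2, 0.3, -0.1), 4)
        contrast = ContrastSpec.single(3, 5, alpha=0.05, label="cl")
        table = multi_test_power(small_layout, mspec, cspec, vspec, [contrast], method="chisq")
        omega = model_covariance(small_layout, mspec, cspec, vspec)
        direct = wald_power(omega, mspec.theta, contrast, small_layout.n_clusters, "chisq")
        assert table["power"][0] == pytest.approx(direct.power, rel=1e-12)

    def test_bonferroni_splits_family_alpha(self, small_layout):
        mspec, cspec, vspec = gaussian_specs((0.0, 0.1, 0.2, 0.3, -0.1), 4)
        contrasts = [
            ContrastSpec.single(2, 5, alpha=None, label="il"),
            ContrastSpec.single(3, 5, alpha=None, label="cl"),
        ]
        table = multi_test_power(
            small_layout, mspec, cspec, vspec, contrasts,
            MultiplicityPlan(family_alpha=0.1), method="chisq",
        )
        assert (table["alpha"] == 0.05).all()

    def test_contradictory_plan_rejected(self):
        contrasts = [ContrastSpec.single(0, 5, alpha=0.05)]
        with pytest.raises(ValueError, match="family"):
            MultiplicityPlan(family_alpha=0.1).resolve(contrasts)

    def test_missing_alpha_rejected(self):
        contrasts = [ContrastSpec.single(0, 5, alpha=None, label="nameless")]
        with pytest.raises(ValueError, match="nameless"):
            MultiplicityPlan().resolve(contrasts)
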