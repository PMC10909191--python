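"""Valence/arousal affect features: identities, symmetries, surrogates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anxeeg.affect import AFFECT_NAMES, ComputationError, affect_features, group_power
from anxeeg.io import ConfigurationError, InputError

FRONTAL = ("AF3", "AF4", "F3", "F4")

power = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def make_powers(values: dict[str, tuple[float, float]]):
    return {ch: {"alpha": a, "beta": b} for ch, (a, b) in values.items()}


def uniform_powers(alpha=1.0, beta=1.0):
    return make_powers({ch: (alpha, beta) for ch in FRONTAL})


@st.composite
def random_powers(draw):
    return make_powers({ch: (draw(power), draw(power)) for ch in FRONTAL})


class TestGroupPower:
    def test_single_channel(self):
        bp = uniform_powers(alpha=2.5)
        assert group_power(bp, ["F3"], "alpha") == 2.5

    def test_additive_and_commutative(self):
        bp = make_powers({"F3": (1.0, 2.0), "F4": (3.0, 5.0)})
        assert group_power(bp, ["F3", "F4"], "beta") == 7.0
        assert group_power(bp, ["F4", "F3"], "beta") == group_power(bp, ["F3", "F4"], "beta")

    def test_unknown_channel_rejected(self):
        with pytest.raises(InputError, match="Cz"):
            group_power(uniform_powers(), ["Cz"], "alpha")


class TestKnownValues:
    def test_unit_powers_symmetry_zeros(self):
        """All band powers 1 ⇒ the asymmetry features vanish; A4 = −2 ln 3."""
        f = affect_features(uniform_powers())
        assert f.valence1 == pytest.approx(0.0)
        assert f.valence2 == pytest.approx(0.0)
        assert f.valence3 == pytest.approx(0.0)
        assert f.valence4 == pytest.approx(0.0)
        assert f.arousal1 == pytest.approx(1.0)
        assert f.arousal2 == pytest.approx(1.0)
        assert f.arousal3 == pytest.approx(0.0)
        assert f.arousal4 == pytest.approx(-2.0 * math.log(3.0))
        assert f.arousal4 == pytest.approx(-2.1972, abs=1e-4)

    def test_hemisphere_swap_antisymmetry(self):
        bp = make_powers({"AF3": (1.0, 2.0), "F3": (3.0, 1.0), "AF4": (2.0, 1.0), "F4": (1.0, 4.0)})
        swapped = make_powers({"AF4": (1.0, 2.0), "F4": (3.0, 1.0), "AF3": (2.0, 1.0), "F3": (1.0, 4.0)})
        f, g = affect_features(bp), affect_features(swapped)
        assert g.valence1 == pytest.approx(-f.valence1)
        assert g.valence2 == pytest.approx(-f.valence2)
        assert g.arousal1 == pytest.approx(f.arousal1)
        assert g.arousal2 == pytest.approx(f.arousal2)
        assert g.arousal3 == pytest.approx(f.arousal3)


class TestProperties:
    @settings(max_examples=1000, derandomize=True, deadline=None)
    @given(random_powers())
    def test_arousal_reciprocal_identity(self, bp):
        f = affect_features(bp)
        assert f.arousal1 * f.arousal2 == pytest.approx(1.0, abs=1e-12, rel=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(random_powers(), st.floats(min_value=1e-2, max_value=1e2))
    def test_scale_invariance_and_log_shifts(self, bp, c):
        """Scaling all powers by c leaves ratio features fixed and shifts the log ones."""
        scaled = {ch: {b: c * v for b, v in d.items()} for ch, d in bp.items()}
        f, g = affect_features(bp), affect_features(scaled)
        assert g.valence1 == pytest.approx(f.valence1, rel=1e-9, abs=1e-9)
        assert g.valence4 == pytest.approx(f.valence4, rel=1e-9, abs=1e-9)
        assert g.arousal1 == pytest.approx(f.arousal1, rel=1e-9)
        assert g.arousal3 == pytest.approx(f.arousal3, rel=1e-6, abs=1e-8)
        assert g.valence2 == pytest.approx(f.valence2, rel=1e-6, abs=1e-8)  # log difference: shift cancels
        assert g.arousal4 == pytest.approx(f.arousal4 - 2.0 * math.log(c), rel=1e-6, abs=1e-8)

    def test_fixed_output_order(self):
        f = affect_features(uniform_powers())
        assert AFFECT_NAMES == (
            "valence1", "valence2", "valence3", "valence4",
            "arousal1", "arousal2", "arousal3", "arousal4",
        )
        assert f.as_array().shape == (8,)
        assert np.isfinite(f.as_array()).all()


class TestFzSurrogate:
    def test_mean_f3_f4_default_matches_manual(self):
        bp = make_powers({"AF3": (1.0, 2.0), "F3": (2.0, 1.0), "AF4": (1.5, 1.0), "F4": (4.0, 2.0)})
        fz_alpha = (2.0 + 4.0) / 2.0
        f = affect_features(bp)
        left = fz_alpha + 1.0 + 2.0
        right = fz_alpha + 1.5 + 4.0
        assert f.valence2 == pytest.approx(math.log(left) - math.log(right))

    def test_explicit_fz_channel_wins(self):
        bp = uniform_powers()
        bp["Fz"] = {"alpha": 9.0, "beta": 1.0}
        f = affect_features(bp)
        assert f.arousal4 == pytest.approx(-2.0 * math.log(11.0))

    def test_drop_term_uses_lateral_channels_only(self):
        f = affect_features(uniform_powers(), fz_surrogate="drop_term")
        assert f.arousal4 == pytest.approx(-2.0 * math.log(2.0))

    def test_unknown_surrogate_rejected(self):
        with pytest.raises(ConfigurationError):
            affect_features(uniform_powers(), fz_surrogate="nearest")


class TestErrors:
    def test_zero_power_names_equation(self):
        bp = uniform_powers()
        bp["F4"]["beta"] = 0.0
        with pytest.raises(ComputationError, match="valence4"):
            affect_features(bp)

    def test_negative_alpha_breaks_log(self):
        bp = uniform_powers()
        bp["AF3"]["alpha"] = -5.0
        with pytest.raises(ComputationError):
            affect_features(bp)
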