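"""Transform, downsample and gating: closed forms, determinism, consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cytoarch as ca
from cytoarch import preprocess as pp
from conftest import pooled_with_truth


def make_sample(values, markers, transformed=True, **kw):
    return pp.SampleMatrix(sample_id=kw.pop("sample_id", "s1"),
                           data=pd.DataFrame(values, columns=markers),
                           transformed=transformed, **kw)


class TestTransform:
    def test_closed_forms(self):
        s = make_sample([[0.0, 5.0]], ["a", "b"], transformed=False)
        t = pp.transform(s, cofactor=5.0)
        assert t.data.iloc[0, 0] == 0.0
        assert t.data.iloc[0, 1] == pytest.approx(np.arcsinh(1.0), abs=1e-12)
        assert t.transformed

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=20, unique=True),
           st.floats(0.1, 100))
    def test_monotonic(self, xs, cofactor):
        s = make_sample([[x] for x in xs], ["m"], transformed=False)
        t = pp.transform(s, cofactor=cofactor).data["m"]
        order = np.argsort(xs)
        assert (np.diff(t.to_numpy()[order]) > 0).all()

    def test_rejects_nonpositive_cofactor_and_double_transform(self):
        s = make_sample([[1.0]], ["m"], transformed=False)
        with pytest.raises(ValueError, match="cofactor"):
            pp.transform(s, cofactor=0)
        with pytest.raises(ValueError, match="already transformed"):
            pp.transform(pp.transform(s))


class TestDownsample:
    def test_exact_target_and_subset(self):
        rng = np.random.default_rng(0)
        s = make_sample(rng.normal(size=(12000, 2)), ["a", "b"])
        d = pp.downsample(s, target=5000, seed=1)
        assert d.n_cells == 5000
        assert set(d.data.index) <= set(s.data.index)
        assert not d.data.index.duplicated().any()

    def test_no_upsampling(self):
        s = make_sample(np.zeros((3000, 1)), ["a"])
        assert pp.downsample(s, target=5000, seed=0) is s

    def test_deterministic_given_seed(self):
        s = make_sample(np.random.default_rng(1).normal(size=(500, 1)), ["a"])
        ids1 = set(pp.downsample(s, 100, seed=9).data.index)
        ids2 = set(pp.downsample(s, 100, seed=9).data.index)
        assert ids1 == ids2

    def test_preserves_subset_frequency_in_expectation(self):
        """Downsampling a 10% subpopulation to 5,000 cells keeps its
        frequency within 1.5 percentage points on average (200 seeds)."""
        n = 10000
        flags = np.zeros(n)
        flags[:1000] = 1.0  # 10% subset
        s = make_sample(flags.reshape(-1, 1), ["flag"])
        devs = [abs(pp.downsample(s, 5000, seed=k).data["flag"].mean() - 0.10)
                for k in range(200)]
        assert np.mean(devs) <= 0.015


MARKERS = ["CD3", "CD14", "CD19", "CD4", "CD8", "TCRVa7.2", "CD161", "CD27"]


def cell(**hi):
    return [3.5 if m in hi else 0.1 for m in MARKERS]


class TestGating:
    def test_canonical_subset_definitions(self):
        cells = [
            cell(**{"CD3": 1, "TCRVa7.2": 1, "CD161": 1}),            # MAIT
            cell(),                                                   # NK/ILC
            cell(CD3=1, CD4=1),                                       # CD4 T
            cell(CD19=1, CD27=1),                                     # B memory
            cell(CD14=1),                                             # monocyte
        ]
        s = make_sample(cells, MARKERS)
        res = pp.gate_subsets(s, pp.default_gate_rules(1.5))
        assert list(res.labels) == ["MAIT", "NK/ILC", "T-CD4", "B-memory",
                                    "Monocyte"]

    def test_frequencies_use_parent_denominator(self):
        cells = [cell(CD3=1, CD4=1)] * 3 + [cell(CD3=1, CD8=1)] + [cell(CD19=1)]
        s = make_sample(cells, MARKERS)
        res = pp.gate_subsets(s, pp.default_gate_rules(1.5))
        f = res.frequencies.set_index("subset")
        assert f.loc["T", "frequency"] == pytest.approx(4 / 5)
        assert f.loc["T-CD4", "n_parent"] == 4
        assert f.loc["T-CD4", "frequency"] == pytest.approx(3 / 4)

    def test_sibling_frequencies_partition_parent(self):
        """B naive/memory split B cells exactly: frequencies sum to 1."""
        rng = np.random.default_rng(3)
        cells = [cell(CD19=1, CD27=1) if rng.random() < 0.4 else cell(CD19=1)
                 for _ in range(50)]
        s = make_sample(cells, MARKERS)
        f = pp.gate_subsets(s, pp.default_gate_rules(1.5)).frequencies
        f = f.set_index("subset")
        assert f.loc["B-naive", "frequency"] + f.loc["B-memory", "frequency"] \
            == pytest.approx(1.0)
        assert f.loc["B-naive", "frequency"] <= 1.0

    def test_gating_recovers_synthetic_truth(self, small_cohort):
        """Well-separated populations gate to their expected subsets >=99%."""
        expected = {"CD4-naive": "T-CD4", "CD4-memory": "T-CD4",
                    "CD4-Th17": "T-CD4", "CD8-naive": "T-CD8",
                    "CD8-effector": "T-CD8", "T-DN": "T-DN", "MAIT": "MAIT",
                    "B-naive": "B-naive", "B-memory": "B-memory",
                    "Plasmablast": "B-memory", "Monocyte": "Monocyte",
                    "NK": "NK/ILC"}
        agree = total = 0
        for s in small_cohort.samples[:4]:
            res = pp.gate_subsets(s, pp.default_gate_rules(1.5))
            truth = small_cohort.truth[s.sample_id].map(expected)
            agree += (res.labels.to_numpy() == truth.to_numpy()).sum()
            total += s.n_cells
        assert agree / total >= 0.99

    def test_missing_marker_named_in_error(self):
        s = make_sample([cell()], MARKERS)
        rule = pp.GateRule("x", (("CD99", "+", 1.0),))
        with pytest.raises(KeyError, match="CD99"):
            pp.gate_subsets(s, [rule])

    def test_transform_gate_consistency(self):
        """Gating transformed data at t equals gating raw data at
        sinh(t) * cofactor (monotonicity of the transform)."""
        rng = np.random.default_rng(5)
        raw = rng.exponential(50, size=(200, len(MARKERS)))
        s_raw = make_sample(raw, MARKERS, transformed=False)
        s_t = pp.transform(s_raw, cofactor=5.0)
        t = 1.5
        rules_t = pp.default_gate_rules(t)
        raw_thr = float(np.sinh(t) * 5.0)
        rules_raw = pp.default_gate_rules(raw_thr)
        lab_t = pp.gate_subsets(s_t, rules_t).labels
        lab_raw = pp.gate_subsets(s_raw, rules_raw).labels
        assert (lab_t.to_numpy() == lab_raw.to_numpy()).all()


class TestMarkerPositiveFraction:
    def test_enumerated_fractions(self):
        vals = [[2.0]] * 4 + [[0.5]] * 6
        s = make_sample(vals, ["PD1"])
        labels = pd.Series(["T"] * 10, index=s.data.index)
        assert pp.marker_positive_fraction(s, labels, "T", "PD1", 1.0) == 0.4
        assert pp.marker_positive_fraction(s, labels, "T", "PD1", 0.1) == 1.0
        assert pp.marker_positive_fraction(s, labels, "T", "PD1", 99.0) == 0.0

    def test_empty_subset_gives_nan(self, caplog):
        s = make_sample([[1.0]], ["PD1"])
        labels = pd.Series(["T"], index=s.data.index)
        with caplog.at_level("WARNING"):
            out = pp.marker_positive_fraction(s, labels, "B", "PD1", 1.0)
        assert np.isnan(out)
        assert "empty" in caplog.text


def test_auto_thresholds_split_bimodal_marker():
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.normal(0.15, 0.3, 500),
                           rng.normal(3.5, 0.3, 500)])
    s = make_sample(vals.reshape(-1, 1), ["CD3"])
    thr = pp.auto_thresholds([s])["CD3"]
    assert 1.0 < thr < 2.7
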