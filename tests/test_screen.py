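"""Query semantics, FC correlation and phenotype classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tfscreen as tfs
from tfscreen.errors import MeasureError, QueryError


def make_fc_table(design_df, strains, measure="normalized_rprot", fc=1.0, p=1.0):
    rows = []
    for s in strains:
        for vid in design_df["variant_id"]:
            rows.append((s, vid, measure, fc, p, p < 0.05))
    return pd.DataFrame(rows, columns=["strain_id", "variant_id", "measure",
                                       "fc", "p_value", "significant"])


def brute_force_query(fc_records, design, c):
    """Exhaustive filter oracle, independent of the query implementation."""
    joined = fc_records.merge(design, on="variant_id")
    joined = joined[joined["measure"] == c.measure]
    col = f"coded_{c.variable}"
    hits = {}
    if c.direction in ("up", "down"):
        for _, r in joined.iterrows():
            if r[col] != c.level or not r["significant"]:
                continue
            if c.direction == "up" and r["fc"] >= 1 + c.fc_margin:
                hits.setdefault(r["strain_id"], []).append(r["fc"])
            if c.direction == "down" and r["fc"] <= 1 - c.fc_margin:
                hits.setdefault(r["strain_id"], []).append(r["fc"])
        key = max if c.direction == "up" else min
        ranked = sorted(((key(v), s) for s, v in hits.items()),
                        key=lambda t: (-t[0] if c.direction == "up" else t[0], t[1]))
        return [(s, k) for k, s in ranked]
    other = [x for x in design.columns if x.startswith("coded_") and x != col]
    for (s, *rest), grp in joined.groupby(["strain_id"] + other):
        lo = grp[grp[col] == -1]
        hi = grp[grp[col] == 1]
        if len(lo) != 1 or len(hi) != 1:
            continue
        flo, fhi = lo["fc"].iloc[0], hi["fc"].iloc[0]
        if not (lo["significant"].iloc[0] and hi["significant"].iloc[0]):
            continue
        opp = (flo >= 1 + c.fc_margin and fhi <= 1 - c.fc_margin) or \
              (fhi >= 1 + c.fc_margin and flo <= 1 - c.fc_margin)
        if opp:
            hits.setdefault(s, []).append(abs(flo - fhi))
    ranked = sorted(((max(v), s) for s, v in hits.items()), key=lambda t: (-t[0], t[1]))
    return [(s, k) for k, s in ranked]


class TestQuery:
    def test_single_hit_up(self, design_df):
        tab = make_fc_table(design_df, ["tf1", "tf2", "tf3"])
        low_oa = design_df.loc[design_df["coded_oxygen"] == -1, "variant_id"]
        sel = (tab.strain_id == "tf1") & tab.variant_id.isin(low_oa)
        tab.loc[sel, ["fc", "p_value", "significant"]] = [1.5, 0.01, True]
        c = tfs.QueryConstraint("normalized_rprot", "up", "oxygen", level=-1)
        out = tfs.query(tab, design_df, c)
        assert list(out["strain_id"]) == ["tf1"]
        assert out["sort_key"].iloc[0] == pytest.approx(1.5)
        assert len(out["conditions"].iloc[0]) == len(low_oa)

    def test_margin_excludes_small_fc(self, design_df):
        tab = make_fc_table(design_df, ["tf1"], fc=1.05, p=0.001)
        c = tfs.QueryConstraint("normalized_rprot", "up", "oxygen", level=-1)
        assert tfs.query(tab, design_df, c).empty

    def test_inverted_toy_ranking(self, design_df):
        tab = make_fc_table(design_df, ["tf_strong", "tf_weak"])
        for strain, (flo, fhi) in [("tf_strong", (1.4, 0.6)), ("tf_weak", (1.2, 0.9))]:
            for lvl, val in [(-1, flo), (1, fhi)]:
                vids = design_df.loc[design_df["coded_pH"] == lvl, "variant_id"]
                sel = (tab.strain_id == strain) & tab.variant_id.isin(vids)
                tab.loc[sel, ["fc", "p_value", "significant"]] = [val, 0.01, True]
        c = tfs.QueryConstraint("normalized_rprot", "inverted", "pH")
        out = tfs.query(tab, design_df, c)
        # tf_weak misses the 10% margin at 0.9 is exactly 1-margin -> included
        assert list(out["strain_id"]) == ["tf_strong", "tf_weak"]
        assert out["sort_key"].iloc[0] == pytest.approx(0.8)

    def test_up_down_disjoint(self, design_df):
        rng = np.random.default_rng(0)
        tab = make_fc_table(design_df, [f"tf{i}" for i in range(5)])
        tab["fc"] = rng.uniform(0.5, 2.0, len(tab))
        tab["p_value"] = rng.uniform(0, 0.1, len(tab))
        tab["significant"] = tab["p_value"] < 0.05
        up = tfs.query(tab, design_df, tfs.QueryConstraint("normalized_rprot", "up", "pH", level=-1))
        down = tfs.query(tab, design_df, tfs.QueryConstraint("normalized_rprot", "down", "pH", level=-1))
        up_conditions = {(s, c["variant_id"]) for s, conds in
                         zip(up["strain_id"], up["conditions"]) for c in conds}
        down_conditions = {(s, c["variant_id"]) for s, conds in
                           zip(down["strain_id"], down["conditions"]) for c in conds}
        assert not (up_conditions & down_conditions)

    @pytest.mark.parametrize("direction,variable,level", [
        ("up", "oxygen", -1), ("down", "temperature", 1), ("inverted", "pH", None),
        ("up", "pH", 0), ("inverted", "carbon", None),
    ])
    def test_matches_brute_force(self, design_df, direction, variable, level):
        """Query engine == exhaustive filter on randomized tables <= 1000 records."""
        rng = np.random.default_rng(hash((direction, variable)) % 2**31)
        tab = make_fc_table(design_df, [f"tf{i}" for i in range(10)])[:1000]
        tab["fc"] = rng.uniform(0.4, 2.5, len(tab))
        tab["p_value"] = rng.uniform(0, 0.2, len(tab))
        tab["significant"] = tab["p_value"] < 0.05
        c = tfs.QueryConstraint("normalized_rprot", direction, variable, level=level)
        out = tfs.query(tab, design_df, c)
        expected = brute_force_query(tab, design_df, c)
        assert list(out["strain_id"]) == [s for s, _ in expected]
        assert list(out["sort_key"]) == pytest.approx([k for _, k in expected])

    def test_inverted_subset_of_up_and_down(self, design_df):
        rng = np.random.default_rng(9)
        tab = make_fc_table(design_df, [f"tf{i}" for i in range(8)])
        tab["fc"] = rng.uniform(0.4, 2.5, len(tab))
        tab["significant"] = True
        tab["p_value"] = 0.01
        inv = tfs.query(tab, design_df, tfs.QueryConstraint("normalized_rprot", "inverted", "pH"))
        up_lo = tfs.query(tab, design_df, tfs.QueryConstraint("normalized_rprot", "up", "pH", level=-1))
        down_hi = tfs.query(tab, design_df, tfs.QueryConstraint("normalized_rprot", "down", "pH", level=1))
        up_hi = tfs.query(tab, design_df, tfs.QueryConstraint("normalized_rprot", "up", "pH", level=1))
        down_lo = tfs.query(tab, design_df, tfs.QueryConstraint("normalized_rprot", "down", "pH", level=-1))
        either = (set(up_lo["strain_id"]) & set(down_hi["strain_id"])) | \
                 (set(up_hi["strain_id"]) & set(down_lo["strain_id"]))
        assert set(inv["strain_id"]) <= either

    def test_unknown_variable(self, design_df):
        tab = make_fc_table(design_df, ["tf1"])
        with pytest.raises(QueryError):
            tfs.query(tab, design_df, tfs.QueryConstraint("normalized_rprot", "up", "salinity", level=-1))


class TestCorrelateFc:
    def test_identities(self):
        x = [0.5, 1.0, 1.5, 2.0]
        assert tfs.correlate_fc(x, x) == pytest.approx(1.0)
        neg = [2.0 * np.mean(x) - v for v in x]
        assert tfs.correlate_fc(x, neg) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.normal(size=rng.integers(3, 30))
            b = rng.normal(size=len(a))
            expected = np.cov(a, b, ddof=1)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
            assert tfs.correlate_fc(a, b) == pytest.approx(expected, abs=1e-12)

    def test_degenerate(self):
        assert np.isnan(tfs.correlate_fc([1, 1, 1], [1, 2, 3]))
        with pytest.raises(QueryError):
            tfs.correlate_fc([1, 2], [1, 2])


class TestClassify:
    def test_control_is_none(self, noisefree_screen, design_df, factors):
        _, _, fc = noisefree_screen
        call = tfs.classify(fc[fc.strain_id == "control"], design_df, factors)
        assert call.label == "none"
        assert call.evidence["mean_growth_fc"] == pytest.approx(1.0)

    @pytest.mark.parametrize("strain,expected", [
        ("tf_global_silencer", "global_rprot_silencer"),
        ("tf_global_enhancer", "global_rprot_enhancer"),
        ("tf_oa_growth_enhancer", "oa_growth_enhancer"),
        ("tf_oa_sensitive", "oa_sensitive"),
        ("tf_null_tf", "none"),
        ("tf_inverted", "none"),
    ])
    def test_noisefree_archetype_rules(self, noisefree_screen, design_df, factors,
                                       strain, expected):
        """Deterministic rule evaluation on noise-free archetype profiles."""
        _, _, fc = noisefree_screen
        call = tfs.classify(fc[fc.strain_id == strain], design_df, factors)
        assert call.label == expected

    def test_oa_enhancer_delta_sign(self, noisefree_screen, design_df, factors):
        _, _, fc = noisefree_screen
        call = tfs.classify(fc[fc.strain_id == "tf_oa_growth_enhancer"], design_df, factors)
        assert call.evidence["low_oa_growth_delta"] > 0

    def test_missing_measure_errors(self, noisefree_screen, design_df, factors):
        _, _, fc = noisefree_screen
        partial = fc[(fc.strain_id == "tf_null_tf") & (fc.measure != "growth")]
        with pytest.raises(MeasureError):
            tfs.classify(partial, design_df, factors)
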