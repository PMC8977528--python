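import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from salpinx.topology import (
    CILIATED,
    SECRETORY,
    ExpansionSummary,
    ROISequence,
    SlideEpithelium,
    call_expansions,
    find_runs,
    group_compare,
    read_cells_csv,
    summaries_frame,
    summarize_slide,
)
from salpinx.topology import fisher_exact_table

S, C = SECRETORY, CILIATED


def roi(labels, roi_id="r0"):
    return ROISequence(roi_id=roi_id, labels=tuple(labels))


def slide(*rois, group="Benign"):
    return SlideEpithelium(case_id="x", region="fimbria", group=group, rois=tuple(rois))


label_seqs = st.lists(st.sampled_from([S, C]), min_size=1, max_size=120)


class TestFindRuns:
    def test_enumerated_example(self):
        runs = find_runs(roi([S, S, C, S]))
        assert [(r.cell_type, r.length, r.start) for r in runs] == [
            (S, 2, 0),
            (C, 1, 2),
            (S, 1, 3),
        ]

    def test_uniform_sequence_single_run(self):
        runs = find_runs(roi([C] * 20))
        assert len(runs) == 1 and runs[0].length == 20

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi([])

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            roi([S, "stromal"])

    @given(label_seqs)
    @settings(max_examples=200, deadline=None)
    def test_lengths_conserve_and_reversal_symmetry(self, labels):
        runs = find_runs(roi(labels))
        assert sum(r.length for r in runs) == len(labels)
        # maximality: adjacent runs differ in type
        for a, b in zip(runs, runs[1:]):
            assert a.cell_type != b.cell_type
        rev = find_runs(roi(labels[::-1]))
        assert sorted((r.cell_type, r.length) for r in runs) == sorted(
            (r.cell_type, r.length) for r in rev
        )


class TestCallExpansions:
    def test_strict_inequality_boundary(self):
        eleven = find_runs(roi([S] * 11))
        ten = find_runs(roi([S] * 10))
        assert len(call_expansions(eleven, 10, S)) == 1
        assert len(call_expansions(ten, 10, S)) == 0

    def test_scout_threshold(self):
        runs = []
        for n in (5, 11, 12, 31):
            runs.extend(find_runs(roi([S] * n, roi_id=f"r{n}")))
        assert len(call_expansions(runs, 30, S)) == 1

    @given(label_seqs, st.integers(min_value=1, max_value=40))
    @settings(max_examples=100, deadline=None)
    def test_threshold_monotonicity(self, labels, thr):
        runs = find_runs(roi(labels))
        assert len(call_expansions(runs, thr + 1, S)) <= len(call_expansions(runs, thr, S))

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            call_expansions([], 0, S)


class TestSummarize:
    def test_hand_enumerated_example(self):
        e = slide(
            roi([S] * 5 + [C] * 2 + [S] * 11, "r0"),
            roi([C] * 12 + [S] * 3, "r1"),
        )
        s = summarize_slide(e)
        assert s.total_cells == 33
        assert s.n_sce == 1 and s.n_cce == 1
        assert math.isclose(s.relative_sce, 1 / 33)
        assert s.mean_cells_in_sce == 11.0
        assert s.mean_cells_in_cce == 12.0

    def test_alternating_sequence_has_no_expansions(self):
        e = slide(roi([S, C] * 50))
        s = summarize_slide(e)
        assert s.n_sce == s.n_cce == 0
        assert s.mean_cells_in_sce is None and s.mean_cells_in_cce is None
        df = summaries_frame([s])
        assert math.isnan(df.mean_cells_in_sce[0])  # missing, never zero

    def test_single_roi_of_twelve_secretory(self):
        s = summarize_slide(slide(roi([S] * 12)))
        assert math.isclose(s.relative_sce, 1 / 12)

    @given(label_seqs.filter(lambda x: len(x) >= 2), st.data())
    @settings(max_examples=150, deadline=None)
    def test_roi_split_properties(self, labels, data):
        whole = summarize_slide(slide(roi(labels)))
        cut = data.draw(st.integers(min_value=1, max_value=len(labels) - 1))
        split = summarize_slide(
            slide(roi(labels[:cut], "a"), roi(labels[cut:], "b"))
        )
        assert split.total_cells == whole.total_cells
        at_boundary = labels[cut - 1] != labels[cut]
        if at_boundary:
            # cutting between two runs changes nothing
            assert (split.n_sce, split.n_cce) == (whole.n_sce, whole.n_cce)
            assert split.mean_cells_in_sce == whole.mean_cells_in_sce
            assert split.mean_cells_in_cce == whole.mean_cells_in_cce
        else:
            # only the run containing the cut is affected; the expansion
            # count changes by exactly (a>10) + (b>10) - (L>10) for the
            # run parts a, b of the original length-L run
            hit = next(
                r for r in find_runs(roi(labels))
                if r.start < cut <= r.start + r.length - 1
            )
            a, b = cut - hit.start, hit.start + hit.length - cut
            delta = (a > 10) + (b > 10) - (hit.length > 10)
            if hit.cell_type == S:
                assert split.n_sce == whole.n_sce + delta
                assert split.n_cce == whole.n_cce
            else:
                assert split.n_cce == whole.n_cce + delta
                assert split.n_sce == whole.n_sce


class TestGroupCompare:
    def test_identical_groups_uninformative(self):
        stat, p = group_compare({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert stat == 0.0 and p == 1.0

    def test_mann_whitney_exhaustive(self):
        stat, p = group_compare({"a": [1, 2, 3], "b": [4, 5, 6]})
        # U = 0; exact two-sided p over all 20 arrangements = 2/20
        assert stat == 0.0
        assert math.isclose(p, 0.1)

    def test_kruskal_matches_scipy_with_ties(self, rng):
        from scipy import stats as ss

        groups = {k: rng.integers(0, 5, 12).astype(float) for k in "abc"}
        stat, p = group_compare(groups)
        ref = ss.kruskal(*[groups[k] for k in sorted(groups)])
        assert math.isclose(stat, ref.statistic)

    def test_paired_dispatch(self, rng):
        x = rng.standard_normal(12)
        y = x + rng.standard_normal(12) * 0.3 + 0.5
        from scipy import stats as ss

        stat, p = group_compare({"pre": x, "post": y}, paired=True)
        ref = ss.wilcoxon(x, y)
        assert math.isclose(stat, ref.statistic)

    def test_fisher_exact_matches_hypergeometric_enumeration(self):
        table = [[8, 2], [1, 5]]
        _, p = fisher_exact_table(table)
        # enumerate all tables with the same margins
        r1, r2 = 10, 6
        c1 = 9
        from scipy.special import comb

        def prob(a):
            return comb(r1, a) * comb(r2, c1 - a) / comb(r1 + r2, c1)

        p0 = prob(8)
        p_exact = sum(prob(a) for a in range(max(0, c1 - r2), min(r1, c1) + 1)
                      if prob(a) <= p0 + 1e-12)
        assert math.isclose(p, p_exact, rel_tol=1e-9)

    def test_missing_values_dropped(self):
        stat, p = group_compare({"a": [1.0, np.nan, 2.0], "b": [3.0, 4.0]})
        assert np.isfinite(p)


def test_cells_csv_round_trip(tmp_path):
    import pandas as pd

    rows = []
    for case, group in (("c1", "Benign"), ("c2", "STIC")):
        for r in range(2):
            labels = [S] * 12 + [C] * 3 if group == "STIC" else [S, C] * 6
            for pos, lab in enumerate(labels):
                rows.append(
                    dict(case_id=case, region="fimbria", group=group,
                         roi_id=f"{case}r{r}", position=pos, cell_type=lab)
                )
    pd.DataFrame(rows).to_csv(tmp_path / "cells.csv", index=False)
    pd.DataFrame(
        [dict(case_id="c1", age=55, menopausal=True, brca=False, chemotherapy=False),
         dict(case_id="c2", age=70, menopausal=True, brca=True, chemotherapy=True)]
    ).to_csv(tmp_path / "cov.csv", index=False)

    slides = read_cells_csv(tmp_path / "cells.csv", tmp_path / "cov.csv")
    assert len(slides) == 2
    by_case = {s.case_id: s for s in slides}
    assert by_case["c2"].age == 70 and by_case["c2"].brca is True
    s = summarize_slide(by_case["c2"])
    assert s.n_sce == 2  # one 12-cell secretory run per ROI
    assert summarize_slide(by_case["c1"]).n_sce == 0


def test_cells_csv_rejects_unknown_labels(tmp_path):
    import pandas as pd

    pd.DataFrame(
        [dict(case_id="c", region="f", group="Benign", roi_id="r", position=0,
              cell_type="lymphocyte")]
    ).to_csv(tmp_path / "bad.csv", index=False)
    with pytest.raises(ValueError, match="invalid cell_type"):
        read_cells_csv(tmp_path / "bad.csv")
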