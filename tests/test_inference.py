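"""Statistical kernels and the crossed random-effects demographic model."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from conftest import tr
from normtext.inference import (
    contingency_test,
    demographic_effects,
    pearson_r,
    same_other_factorial,
    welch_t,
)
from normtext.scoring import SharedWordResult


def _welch_formula(x, y):
    """Textbook Welch statistic and Satterthwaite df, computed from scratch."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return t, df


def test_welch_t_matches_formula():
    rng = np.random.default_rng(2)
    for _ in range(10):
        x = rng.normal(0, 1, size=rng.integers(5, 40))
        y = rng.normal(0.3, 2, size=rng.integers(5, 40))
        t, df, p = welch_t(x, y)
        t0, df0 = _welch_formula(x, y)
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == pytest.approx(df0, abs=1e-10)
        assert 0 <= p <= 1


def test_welch_t_degenerate():
    x = [1.0, 2.0, 3.0]
    t, _, p = welch_t(x, x)
    assert t == pytest.approx(0.0)
    with pytest.raises(ValueError):
        welch_t([0.0, 0.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])


def test_pearson_r():
    x = np.arange(10.0)
    r, p = pearson_r(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r, _ = pearson_r(x, -3 * x + 2)
    assert r == pytest.approx(-1.0)
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=50), rng.normal(size=50)
    r, _ = pearson_r(a, b)
    ra = np.corrcoef(a, b)[0, 1]
    assert r == pytest.approx(ra, abs=1e-10)
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])


def test_contingency_chi2():
    stat, df, p = contingency_test([[10, 0], [0, 10]])
    assert stat == pytest.approx(20.0)  # perfect association: chi2 = N
    assert df == 1
    stat, _, _ = contingency_test([[5, 5], [5, 5]])
    assert stat == pytest.approx(0.0)
    with pytest.raises(ValueError):
        contingency_test([[0, 0], [0, 0]])
    with pytest.raises(ValueError):
        contingency_test([[1.5, 2], [3, 4]])


def test_contingency_demographic_table():
    """The one checkable published group-comparison p-value (Hispanic counts)."""
    with pytest.warns(UserWarning):  # an expected count is below 5
        stat, df, p = contingency_test([[8, 91], [1, 59]])
    assert round(p, 2) == 0.09
    odds, _, pf = contingency_test([[8, 91], [1, 59]], method="fisher")
    assert 0 <= pf <= 1 and odds > 1


def _fake_results(rng, n, dataset, same_mu, other_mu):
    out = []
    for i in range(n):
        out.append(
            SharedWordResult(
                response_id=f"{dataset}{i}",
                clip_id=f"c{i % 5}",
                dataset_label=dataset,
                mean_same=float(rng.normal(same_mu, 1)),
                mean_other=float(rng.normal(other_mu, 1)),
                n_same=10,
                n_other=100,
            )
        )
    return out


def test_factorial_cell_means_and_effects():
    rng = np.random.default_rng(8)
    res = _fake_results(rng, 300, "A", 5, 2) + _fake_results(rng, 300, "B", 4, 2)
    fact = same_other_factorial(res)
    # cell means reproduce directly computed grand means
    for ds, comp, mu in (("A", "same", 5), ("A", "other", 2), ("B", "same", 4)):
        vals = [
            (r.mean_same if comp == "same" else r.mean_other)
            for r in res
            if r.dataset_label == ds
        ]
        cell = fact.cell_means.query("dataset == @ds and comparison == @comp")["score"]
        assert cell.iloc[0] == pytest.approx(np.mean(vals))
    assert fact.p_comparison < 1e-6
    assert fact.f_interaction > 0  # same/other gap differs between A and B


def test_factorial_identical_distributions_interaction_null():
    rng = np.random.default_rng(12)
    res = _fake_results(rng, 400, "A", 3, 1) + _fake_results(rng, 400, "B", 3, 1)
    fact = same_other_factorial(res)
    assert fact.p_interaction > 0.01  # no real interaction injected


def test_factorial_single_dataset_reduces_to_paired():
    rng = np.random.default_rng(4)
    res = _fake_results(rng, 100, "A", 3, 1)
    with pytest.warns(UserWarning, match="single dataset"):
        fact = same_other_factorial(res)
    assert fact.f_comparison > 0 and math.isnan(fact.f_dataset)
    assert fact.df_num == 1


def test_factorial_constant_scores_error():
    res = [
        SharedWordResult(f"r{i}", "c", "A", 1.0, 1.0, 5, 5) for i in range(10)
    ]
    with pytest.raises(ValueError):
        same_other_factorial(res)


def _demo_frame(rng, n_part=24, n_clips=8, reps=4, age_beta=0.0, male_beta=0.0):
    rows = []
    part_int = rng.normal(0, 0.5, n_part)
    clip_int = rng.normal(0, 0.5, n_clips)
    ages = rng.uniform(20, 70, n_part)
    males = rng.random(n_part) < 0.5
    edu = rng.integers(1, 6, n_part)
    k = 0
    for p in range(n_part):
        for c in rng.choice(n_clips, size=reps, replace=False):
            y = (
                5 + age_beta * ages[p] + male_beta * males[p]
                + part_int[p] + clip_int[c] + rng.normal(0, 1)
            )
            rows.append((f"r{k}", f"p{p}", f"c{c}", ages[p],
                         "male" if males[p] else "female", edu[p], y))
            k += 1
    return pd.DataFrame(
        rows, columns=["response_id", "participant_id", "clip_id", "age",
                       "gender", "education", "mean_same"]
    )


def test_demographic_effects_constant_outcome():
    df = _demo_frame(np.random.default_rng(1))
    df["mean_same"] = 3.25
    ests = {e.term: e for e in demographic_effects(df, "mean_same")}
    assert ests["intercept"].coefficient == pytest.approx(3.25)
    for term in ("age", "male", "education"):
        assert ests[term].coefficient == 0.0


def test_demographic_effects_validation():
    df = _demo_frame(np.random.default_rng(1))
    with pytest.raises(ValueError, match="missing columns"):
        demographic_effects(df.drop(columns=["age"]), "mean_same")
    allf = df.copy()
    allf["gender"] = "female"  # constant dummy -> collinear with intercept
    with pytest.raises(ValueError, match="collinear"):
        demographic_effects(allf, "mean_same")


def test_demographic_effects_matches_lme4():
    """Cross-check the crossed-VC construction against R lme4 (REML)."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    df = _demo_frame(np.random.default_rng(77), age_beta=0.03, male_beta=-0.5)
    ests = {e.term: e for e in demographic_effects(df, "mean_same")}
    csv = df.to_csv(index=False)
    script = textwrap.dedent(
        """
        suppressMessages(library(lme4))
        d <- read.csv("stdin")
        d$male <- as.numeric(d$gender == "male")
        d$age_c <- d$age - mean(d$age)
        m <- lmer(mean_same ~ age_c + male + education
                  + (1|participant_id) + (1|clip_id), data=d, REML=TRUE)
        co <- summary(m)$coefficients
        write.csv(data.frame(term=rownames(co), est=co[,1], se=co[,2]), row.names=FALSE)
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", script], input=csv, capture_output=True, text=True,
        check=True,
    )
    r = pd.read_csv(pd.io.common.StringIO(out.stdout)).set_index("term")
    for ours, theirs in (("age", "age_c"), ("male", "male"),
                         ("education", "education")):
        assert ests[ours].coefficient == pytest.approx(
            r.loc[theirs, "est"], rel=2e-3, abs=1e-4
        )
        assert ests[ours].standard_error == pytest.approx(
            r.loc[theirs, "se"], rel=5e-3, abs=1e-4
        )


def test_demographic_effects_metadata_and_ml():
    df = _demo_frame(np.random.default_rng(5), age_beta=0.05)
    reml = demographic_effects(df, "mean_same")
    ml = demographic_effects(df, "mean_same", reml=False)
    assert reml[0].metadata["method"] == "REML"
    assert ml[0].metadata["method"] == "ML"
    age = [e for e in reml if e.term == "age"][0]
    assert age.conf_low < age.coefficient < age.conf_high
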