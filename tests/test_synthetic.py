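"""The synthetic study generator: reproducibility, design constraints,
and calibration of the structures the scoring analysis assumes."""

import numpy as np
import pandas as pd
import pytest

from normtext import io as nio
from normtext import scoring
from normtext.synthetic import (
    DatasetConfig,
    GeneratorConfig,
    _free_volumes,
    _zipf_probs,
    generate_participants,
    generate_study,
    generate_vocabularies,
)
from normtext.textprep import default_stopwords, tokenized_response


def small_config(seed=0, **kw):
    ds_a = DatasetConfig(
        label="a", responses_per_clip=4, n_participants=8, length_mean=12.0,
        score_effects={}, length_effects={}, participant_score_sd=0.0,
    )
    ds_b = DatasetConfig(
        label="b", responses_per_clip=4, n_participants=6,
        participant_assignment="balanced", clips_per_participant=4,
        length_mean=10.0, age_bands=((20, 40),), score_effects={},
        length_effects={}, participant_score_sd=0.0,
    )
    defaults = dict(n_clips=6, clip_vocab_size=8, global_vocab_size=60,
                    datasets=(ds_a, ds_b), seed=seed)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


def tokenize_bundle(bundle, label=None):
    sl = default_stopwords()
    df = bundle.responses
    if label is not None:
        df = df[df.dataset == label]
    return [tokenized_response(r, sl) for r in nio.responses_from_frame(df)]


def test_vocabularies_disjoint_and_deterministic():
    cfg = small_config(seed=4)
    v1 = generate_vocabularies(cfg)
    v2 = generate_vocabularies(cfg)
    assert v1.clip_words == v2.clip_words
    assert v1.clip_exponents == v2.clip_exponents
    all_topic = [w for ws in v1.clip_words.values() for w in ws]
    assert len(all_topic) == len(set(all_topic)) == 6 * 8
    assert not set(all_topic) & set(v1.background)
    assert not (set(all_topic) | set(v1.background)) & default_stopwords().words


def test_zipf_concentration():
    # steep exponent concentrates the mass on rank 1
    probs = _zipf_probs(100, 4.0)
    assert probs[0] >= 0.9
    assert np.isclose(probs.sum(), 1.0)
    flat = _zipf_probs(100, 0.0)
    assert np.allclose(flat, 0.01)


def test_participants_balanced_design():
    cfg = GeneratorConfig(seed=1)
    lab = generate_participants(cfg, "labsourced")
    assert len(lab) == 60
    assert (lab.gender == "male").sum() == 30
    # equal cells across age band x gender
    assert lab.groupby("cell").size().nunique() == 1
    ages = lab.age
    assert ages.between(23, 85).all()


def test_participants_crowdsourced_shape():
    cfg = GeneratorConfig(seed=2)
    crowd = generate_participants(cfg, "crowdsourced")
    assert len(crowd) == 99
    assert crowd.age.between(20, 66).all()
    assert 0.4 < (crowd.gender == "female").mean() < 0.85
    assert crowd.education.between(1, 5).all()


def test_participants_latents_independent_when_no_effects():
    ds = DatasetConfig(n_participants=5000, score_effects={}, length_effects={})
    cfg = GeneratorConfig(datasets=(ds,), seed=3)
    part = generate_participants(cfg, ds)
    assert abs(np.corrcoef(part.age, part.score_intercept)[0, 1]) < 0.05
    assert abs(np.corrcoef(part.age, part.verbosity)[0, 1]) < 0.05
    assert (part.score_shift == 0).all()


def test_participants_validation_and_determinism():
    ds = DatasetConfig(female_prop=1.7)
    cfg = GeneratorConfig(datasets=(ds,), seed=0)
    with pytest.raises(ValueError, match="proportion"):
        generate_participants(cfg, ds)
    cfg2 = small_config(seed=9)
    a = generate_participants(cfg2, "a")
    b = generate_participants(cfg2, "a")
    pd.testing.assert_frame_equal(a, b)


def test_free_assignment_constraints():
    bundle = generate_study(small_config(seed=5))
    resp = bundle.responses[bundle.responses.dataset == "a"]
    # every clip filled to exactly responses_per_clip
    assert (resp.groupby("clip_id").size() == 4).all()
    # no participant sees a clip twice
    assert not resp.duplicated(["participant_id", "clip_id"]).any()


def test_balanced_assignment_constraints():
    bundle = generate_study(small_config(seed=5))
    resp = bundle.responses[bundle.responses.dataset == "b"]
    assert (resp.groupby("clip_id").size() == 4).all()
    assert (resp.groupby("participant_id").size() == 4).all()
    assert not resp.duplicated(["participant_id", "clip_id"]).any()
    # per-cell coverage of each clip is equal (2 cells x 2 responses here)
    part = bundle.participants.set_index("participant_id")
    cells = resp.participant_id.map(part.cell)
    per = resp.assign(cell=cells).groupby(["clip_id", "cell"]).size()
    assert per.nunique() == 1


def test_balanced_infeasible_configs_error():
    bad = DatasetConfig(
        label="b", participant_assignment="balanced", n_participants=6,
        clips_per_participant=5, responses_per_clip=4, age_bands=((20, 40),),
    )
    cfg = GeneratorConfig(n_clips=6, clip_vocab_size=4, global_vocab_size=30,
                          datasets=(bad,))
    with pytest.raises(ValueError, match="balanced"):
        generate_study(cfg)
    with pytest.raises(ValueError, match="divisible"):
        generate_participants(cfg, DatasetConfig(
            participant_assignment="balanced", n_participants=7))


def test_study_reproducible_and_files(tmp_path):
    cfg = small_config(seed=11)
    b1 = generate_study(cfg, tmp_path / "run1")
    b2 = generate_study(small_config(seed=11), tmp_path / "run2")
    pd.testing.assert_frame_equal(b1.responses, b2.responses)
    pd.testing.assert_frame_equal(b1.participants, b2.participants)
    f1 = (tmp_path / "run1" / "responses.csv").read_bytes()
    f2 = (tmp_path / "run2" / "responses.csv").read_bytes()
    assert f1 == f2
    assert (tmp_path / "run1" / "truth.json").exists()
    b3 = generate_study(small_config(seed=12))
    assert not b3.responses.equals(b1.responses)


def test_default_config_counts():
    bundle = generate_study(GeneratorConfig(seed=0))
    sizes = bundle.responses.groupby("dataset").size()
    assert sizes["crowdsourced"] == 4000
    assert sizes["labsourced"] == 2400
    assert len(bundle.participants) == 99 + 60
    lab = bundle.responses[bundle.responses.dataset == "labsourced"]
    assert (lab.groupby("participant_id").size() == 40).all()


def test_full_signal_disjoint_vocab_zero_other():
    """rho=1 with disjoint clip vocabularies forces mean_other = 0."""
    cfg = small_config(seed=6, clip_signal=1.0)
    tok = tokenize_bundle(generate_study(cfg), "a")
    for r in scoring.take_one_out(tok):
        assert r.mean_other == 0.0


def test_productivity_tail_share():
    """Top 20% of free-mode participants contribute about 60% of responses."""
    ds = DatasetConfig()
    shares = []
    for seed in range(8):
        v = np.sort(_free_volumes(ds, 200, 4000, np.random.default_rng(seed)))
        top = int(np.ceil(0.2 * len(v)))
        shares.append(v[-top:].sum() / v.sum())
        assert v.min() >= 1 and v.max() <= 200 and v.sum() == 4000
    assert 0.55 < np.mean(shares) < 0.65
    assert all(0.45 < s < 0.72 for s in shares)


def test_smoke_config_is_fast():
    import time

    t0 = time.perf_counter()
    ds = DatasetConfig(label="a", responses_per_clip=3, n_participants=5,
                       length_mean=8.0)
    cfg = GeneratorConfig(n_clips=5, clip_vocab_size=5, global_vocab_size=30,
                          datasets=(ds,), seed=1)
    bundle = generate_study(cfg)
    assert len(bundle.responses) == 15
    assert time.perf_counter() - t0 < 10.0
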