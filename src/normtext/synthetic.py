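"""Synthetic normative-response studies.

Real normative corpora of clip descriptions are rarely shareable, so this
module generates synthetic studies with the statistical structure the
analysis pipeline assumes:

* a **background vocabulary** with Zipf-distributed frequencies shared by all
  clips (the common descriptive vocabulary), with a per-dataset exponent so
  one dataset can use a flatter — more varied — vocabulary than the other;
* a **topic vocabulary per clip**, pairwise disjoint across clips, from which
  each content token is drawn with a clip-specific probability rho_c.  The
  per-clip signal is drawn around ``clip_signal`` on the logit scale and is
  shared by every dataset — clips genuinely differ in how much common
  vocabulary they elicit, which makes per-clip homogeneity correlate across
  datasets; clips also differ in how concentrated their topic-word
  frequencies are;
* **participants** with demographics (age, gender, ordinal education) and
  latent verbosity and conformity, assigned to clips either ``free`` (workers
  choose their own volume, heavy-tailed so the most prolific 20% contribute
  roughly 60% of responses) or ``balanced`` (a fixed number of clips each,
  with equal clip coverage by demographic cell);
* **response lengths** from an over-dispersed negative-binomial distribution
  around a per-dataset mean;
* **injectable demographic effects** specified directly in outcome units
  (shared words of score, or words of length).  Length effects add to the
  participant's length mean; score effects are realised by inverting the
  expected-score-vs-length curve (see :func:`length_score_curve`), so that
  configured coefficients are recoverable by the inference module on the
  score scale.

Emitted "text" is space-joined synthetic tokens with stopwords interleaved at
a configurable rate, so the full preprocessing path (tokenisation, stopword
removal) is exercised end to end.  Everything is reproducible from the
config seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DatasetConfig",
    "GeneratorConfig",
    "Vocabularies",
    "TruthRecord",
    "StudyBundle",
    "generate_vocabularies",
    "generate_participants",
    "generate_responses",
    "generate_study",
    "default_config",
]

# stopword tokens interleaved into synthetic text; all are on the packaged list
_FILLERS = np.array(
    ["the", "a", "and", "of", "is", "to", "in", "it", "that", "was",
     "um", "uh", "yeah", "okay"]
)


@dataclass
class DatasetConfig:
    """Design of one dataset within a study.

    Defaults for the two shipped presets emulate a crowdsourced collection
    (99 workers choosing their own volume, 20 responses per clip, longer
    typed responses, a younger age distribution, more women) and a lab
    collection (60 participants, 40 clips each giving 12 per clip, shorter
    transcribed spoken responses, an age-stratified balanced design).
    Demographic effects are in outcome units: score effects in shared words
    per predictor unit, length effects in words per predictor unit.
    """

    label: str = "crowdsourced"
    responses_per_clip: int = 20
    n_participants: int = 99
    participant_assignment: str = "free"  # "free" | "balanced"
    clips_per_participant: int = 40  # balanced mode only
    length_mean: float = 33.0
    length_dispersion: float = 12.0  # negative-binomial shape; larger = tighter
    zipf_exponent: float = 1.10  # background frequency decay; lower = more varied
    productivity_sigma: float = 1.5  # log-sd of free-mode response volumes
    age_range: tuple[int, int] = (20, 66)
    age_median: float = 35.0
    age_bands: tuple[tuple[int, int], ...] = ((23, 59), (60, 70), (71, 85))
    female_prop: float = 0.63  # free mode; balanced mode splits genders exactly
    education_probs: tuple[float, ...] = (0.11, 0.16, 0.32, 0.28, 0.13)
    score_effects: dict = field(
        default_factory=lambda: {"age": 0.0, "male": 0.0, "education": 0.0}
    )
    length_effects: dict = field(
        default_factory=lambda: {"age": 0.0, "male": 0.0, "education": 0.0}
    )
    participant_score_sd: float = 0.5  # random intercept on the score scale
    verbosity_sigma: float = 0.25  # log-sd of the length multiplier


def _crowdsourced_default() -> DatasetConfig:
    return DatasetConfig(
        score_effects={"age": 0.027, "male": -0.61, "education": 0.0},
    )


def _labsourced_default() -> DatasetConfig:
    return DatasetConfig(
        label="labsourced",
        responses_per_clip=12,
        n_participants=60,
        participant_assignment="balanced",
        clips_per_participant=40,
        length_mean=28.0,
        zipf_exponent=1.00,
        age_range=(23, 85),
        female_prop=0.5,
        education_probs=(0.083, 0.10, 0.033, 0.334, 0.45),
        score_effects={"age": -0.013, "male": 0.0, "education": 0.0},
        length_effects={"age": 0.0, "male": 0.0, "education": 2.3},
    )


@dataclass
class GeneratorConfig:
    """Full parameterisation of a synthetic study."""

    n_clips: int = 200
    clip_vocab_size: int = 40
    global_vocab_size: int = 6000
    clip_zipf_range: tuple[float, float] = (0.7, 1.3)
    clip_signal: float = 0.5  # rho: P(content token is a clip-topic word)
    clip_signal_sd: float = 1.3  # logit-scale spread of the per-clip signal
    stopword_rate: float = 0.45  # fraction of raw tokens that are stopwords
    prompt_split: float = 0.7  # share of tokens placed in the first prompt
    datasets: tuple[DatasetConfig, ...] = field(
        default_factory=lambda: (_crowdsourced_default(), _labsourced_default())
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.clip_signal <= 1.0:
            raise ValueError("clip_signal must be in [0, 1]")
        for name in ("n_clips", "clip_vocab_size", "global_vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_clips * self.clip_vocab_size + self.global_vocab_size > 5_000_000:
            raise ValueError("requested vocabulary exceeds the token name space")


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The study-shaped default configuration with a given seed."""
    return GeneratorConfig(seed=seed, **overrides)


@dataclass(frozen=True)
class Vocabularies:
    """Realised background and per-clip topic vocabularies."""

    background: tuple[str, ...]
    clip_ids: tuple[str, ...]
    clip_words: dict  # clip_id -> tuple of words
    clip_probs: dict  # clip_id -> np.ndarray of within-topic probabilities
    clip_exponents: dict  # clip_id -> float
    clip_rho: dict  # clip_id -> realised clip signal (shared by all datasets)


@dataclass
class TruthRecord:
    """Ground truth of a generated study, sufficient for recovery tests."""

    seed: int
    config: dict
    clip_exponents: dict
    clip_rho: dict  # realised per-clip signal, shared across datasets
    score_slopes: dict  # dataset label -> d E[mean_same] / d words of length
    clip_words: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


@dataclass
class StudyBundle:
    responses: pd.DataFrame
    participants: pd.DataFrame
    truth: TruthRecord

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "responses": out / "responses.csv",
            "participants": out / "participants.csv",
            "truth": out / "truth.json",
        }
        self.responses.to_csv(paths["responses"], index=False)
        self.participants.to_csv(paths["participants"], index=False)
        self.truth.to_json(paths["truth"])
        return paths


def _alpha_code(i: int, width: int = 3) -> str:
    """Letters-only base-26 encoding, so synthetic tokens survive tokenisation."""
    s = ""
    for _ in range(width):
        s = chr(ord("a") + i % 26) + s
        i //= 26
    if i:
        raise ValueError("index exceeds the token name space")
    return s


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def generate_vocabularies(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> Vocabularies:
    """Build the background vocabulary and pairwise-disjoint clip vocabularies.

    Token names are synthetic (``bg00042``, ``clip017w03``) and therefore
    disjoint from any English stopword list.  Deterministic under the config
    seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bg = tuple(f"bg{_alpha_code(i, 4)}" for i in range(config.global_vocab_size))
    lo, hi = config.clip_zipf_range
    clip_ids = tuple(f"clip{c:03d}" for c in range(config.n_clips))
    exponents = {c: float(rng.uniform(lo, hi)) for c in clip_ids}
    clip_words = {
        c: tuple(
            f"top{_alpha_code(ci, 3)}{_alpha_code(j, 2)}"
            for j in range(config.clip_vocab_size)
        )
        for ci, c in enumerate(clip_ids)
    }
    clip_probs = {
        c: _zipf_probs(config.clip_vocab_size, exponents[c]) for c in clip_ids
    }
    # clips differ in how much common vocabulary they elicit; the per-clip
    # signal is a latent property of the clip itself, shared by every dataset
    # (it is what makes clip homogeneity correlate across datasets)
    rho0 = config.clip_signal
    if 0.0 < rho0 < 1.0 and config.clip_signal_sd > 0:
        eta = rng.normal(0.0, config.clip_signal_sd, size=config.n_clips)
        logit = math.log(rho0 / (1.0 - rho0)) + eta
        rhos = 1.0 / (1.0 + np.exp(-logit))
    else:
        rhos = np.full(config.n_clips, rho0)
    clip_rho = {c: float(r) for c, r in zip(clip_ids, rhos)}
    return Vocabularies(
        background=bg,
        clip_ids=clip_ids,
        clip_words=clip_words,
        clip_probs=clip_probs,
        clip_exponents=exponents,
        clip_rho=clip_rho,
    )


def generate_participants(
    config: GeneratorConfig,
    dataset: DatasetConfig | str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample a participant table with demographics and latent parameters.

    Free mode draws ages from a shifted lognormal calibrated to the
    configured median (a young mode with a long older tail) and gender from
    the configured proportion.  Balanced mode stratifies participants into
    age-band x gender cells of equal size, with ages uniform within band.
    Latent columns: ``verbosity`` (multiplies the length mean, lognormal with
    unit mean), ``score_intercept`` (participant random intercept in score
    units), and the deterministic demographic shifts ``score_shift`` and
    ``length_shift`` implied by the configured effect coefficients.
    """
    if isinstance(dataset, str):
        matches = [d for d in config.datasets if d.label == dataset]
        if not matches:
            raise ValueError(f"no dataset labelled {dataset!r} in config")
        dataset = matches[0]
    ds = dataset
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = ds.n_participants
    if not 0.0 <= ds.female_prop <= 1.0:
        raise ValueError("female_prop must be a proportion in [0, 1]")
    if any(p < 0 for p in ds.education_probs) or sum(ds.education_probs) <= 0:
        raise ValueError("education_probs must be nonnegative and sum > 0")

    if ds.participant_assignment == "balanced":
        n_cells = 2 * len(ds.age_bands)
        if n % n_cells:
            raise ValueError(
                f"balanced mode needs n_participants divisible by {n_cells}"
            )
        per_cell = n // n_cells
        ages, genders, cells = [], [], []
        for bi, (lo, hi) in enumerate(ds.age_bands):
            for gi, g in enumerate(("female", "male")):
                ages.extend(rng.integers(lo, hi + 1, size=per_cell).tolist())
                genders.extend([g] * per_cell)
                cells.extend([bi * 2 + gi] * per_cell)
        ages = np.array(ages, dtype=float)
        genders = np.array(genders)
        cells = np.array(cells)
    else:
        lo, hi = ds.age_range
        mu = math.log(ds.age_median - lo) if ds.age_median > lo else 0.0
        ages = lo + rng.lognormal(mu, 0.55, size=n)
        ages = np.clip(np.round(ages), lo, hi).astype(float)
        genders = np.where(rng.random(n) < ds.female_prop, "female", "male")
        cells = np.full(n, -1)

    probs = np.asarray(ds.education_probs, dtype=float)
    probs = probs / probs.sum()
    education = rng.choice(np.arange(1, len(probs) + 1), size=n, p=probs)
    verbosity = rng.lognormal(
        -0.5 * ds.verbosity_sigma**2, ds.verbosity_sigma, size=n
    )
    score_intercept = rng.normal(0.0, ds.participant_score_sd, size=n)

    # effects centered at the realised sample means, so injected coefficients
    # tilt individuals without moving the dataset-level length/score means
    male = (genders == "male").astype(float)
    se, le = ds.score_effects, ds.length_effects
    age_c = ages - ages.mean()
    male_c = male - male.mean()
    edu_c = education - education.mean()
    score_shift = (
        se.get("age", 0.0) * age_c
        + se.get("male", 0.0) * male_c
        + se.get("education", 0.0) * edu_c
    )
    length_shift = (
        le.get("age", 0.0) * age_c
        + le.get("male", 0.0) * male_c
        + le.get("education", 0.0) * edu_c
    )
    return pd.DataFrame(
        {
            "participant_id": [f"{ds.label[:4]}p{i:04d}" for i in range(n)],
            "dataset": ds.label,
            "age": ages,
            "gender": genders,
            "education": education,
            "cell": cells,
            "verbosity": verbosity,
            "score_intercept": score_intercept,
            "score_shift": score_shift,
            "length_shift": length_shift,
        }
    )


def _length_grid(ds: DatasetConfig) -> tuple[np.ndarray, np.ndarray]:
    """Marginal content-length pmf: negative binomial mixed over the lognormal
    participant verbosity multiplier (Gauss-Hermite quadrature)."""
    k = ds.length_dispersion
    nodes, weights = np.polynomial.hermite_e.hermegauss(15)
    verb = np.exp(-0.5 * ds.verbosity_sigma**2 + ds.verbosity_sigma * nodes)
    weights = weights / weights.sum()
    means = np.maximum(2.0, ds.length_mean * verb)
    p_hi = k / (k + means.max())
    hi = int(stats.nbinom.ppf(0.9995, k, p_hi)) + 1
    lengths = np.arange(hi + 1)
    pmf = np.zeros_like(lengths, dtype=float)
    for w, m in zip(weights, means):
        pmf += w * stats.nbinom.pmf(lengths, k, k / (k + m))
    return lengths.astype(float), pmf / pmf.sum()


def _phi(per_token_prob: np.ndarray, lengths: np.ndarray, pmf: np.ndarray) -> np.ndarray:
    """E over response length L of P(word appears at least once) per word."""
    miss = (1.0 - per_token_prob)[None, :] ** lengths[:, None]
    return 1.0 - pmf @ miss


def expected_same_score(
    rho_self: float,
    rho_pop: float,
    clip_q: np.ndarray,
    bg_p: np.ndarray,
    lengths: np.ndarray,
    pmf: np.ndarray,
) -> float:
    """Expected shared-word count between a response with topic probability
    ``rho_self`` and a same-clip response at the population ``rho_pop``.

    Sums, over topic and background words, the product of each side's
    appearance probabilities, with response length integrated over its
    distribution.  Word appearances are treated as independent given length,
    which is accurate for the small per-word token probabilities used here.
    """
    t = float(_phi(rho_self * clip_q, lengths, pmf)
              @ _phi(rho_pop * clip_q, lengths, pmf))
    b = float(_phi((1 - rho_self) * bg_p, lengths, pmf)
              @ _phi((1 - rho_pop) * bg_p, lengths, pmf))
    return t + b


def score_slope(config: GeneratorConfig, ds: DatasetConfig) -> float:
    """Sensitivity of the expected same-clip score to rho, d E[score]/d rho.

    A diagnostic of how strongly the clip signal drives same-clip sharing,
    evaluated at the population rho with the dataset's length distribution.
    """
    rho_grid, score_grid = score_curve(config, ds)
    rho = config.clip_signal
    h = min(0.02, max(rho, 1e-3) / 2, max(1 - rho, 1e-3) / 2)
    return float(
        (np.interp(rho + h, rho_grid, score_grid)
         - np.interp(rho - h, rho_grid, score_grid)) / (2 * h)
    )


def score_curve(
    config: GeneratorConfig, ds: DatasetConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Expected same-clip score as a function of an individual's rho, with the
    comparison side held at the population rho.

    Averaged over the clip-concentration range.  Rises steeply at low rho
    and peaks below rho = 1 (as rho grows the background contribution to
    sharing vanishes faster than the topic contribution saturates); a
    diagnostic of the score-signal relationship, not an injection channel —
    score-unit effects are injected through :func:`length_score_curve`.
    """
    key = (
        config.clip_vocab_size, config.global_vocab_size, config.clip_zipf_range,
        config.clip_signal, ds.zipf_exponent, ds.length_mean,
        ds.length_dispersion, ds.verbosity_sigma,
    )
    cached = _CURVE_CACHE.get(key)
    if cached is not None:
        return cached
    lo, hi = config.clip_zipf_range
    bg_p = _zipf_probs(config.global_vocab_size, ds.zipf_exponent)
    lengths, pmf = _length_grid(ds)
    rho0 = config.clip_signal
    rho_grid = np.linspace(0.005, 0.995, 100)
    phi_pop_b = _phi((1 - rho0) * bg_p, lengths, pmf)
    # background term is exponent-independent; compute once per grid point
    bg_scores = np.array(
        [float(_phi((1 - r) * bg_p, lengths, pmf) @ phi_pop_b) for r in rho_grid]
    )
    topic_scores = np.zeros_like(rho_grid)
    exps = np.linspace(lo, hi, 7)
    for e in exps:
        clip_q = _zipf_probs(config.clip_vocab_size, e)
        phi_pop_t = _phi(rho0 * clip_q, lengths, pmf)
        phi_self = _phi(
            (rho_grid[:, None] * clip_q[None, :]).ravel(), lengths, pmf
        ).reshape(len(rho_grid), -1)
        topic_scores += phi_self @ phi_pop_t
    out = (rho_grid, topic_scores / len(exps) + bg_scores)
    _CURVE_CACHE[key] = out
    return out


_CURVE_CACHE: dict = {}


def _phi_nbinom(pi: np.ndarray, m: float, k: float) -> np.ndarray:
    """P(word appears >= once) for per-token probability ``pi`` when response
    length is negative binomial with mean ``m`` and shape ``k`` (closed form
    via the probability generating function)."""
    p = k / (k + m)
    return 1.0 - (p / (1.0 - (1.0 - p) * (1.0 - pi))) ** k


def length_score_curve(
    config: GeneratorConfig, ds: DatasetConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Expected same-clip score as a function of a response's mean length.

    Monotone increasing and far from saturation at realistic lengths, which
    makes it the generator's channel for injecting score-unit demographic
    effects: a participant's length mean is placed on this curve so that
    their *expected score* moves by exactly the configured shift.  (Longer
    responses sharing more words with the normative corpus is also the
    dominant empirical regularity of this scoring method.)  The comparison
    side integrates the population verbosity mixture at the population rho.
    """
    key = (
        "len", config.clip_vocab_size, config.global_vocab_size,
        config.clip_zipf_range, config.clip_signal, ds.zipf_exponent,
        ds.length_mean, ds.length_dispersion, ds.verbosity_sigma,
    )
    cached = _CURVE_CACHE.get(key)
    if cached is not None:
        return cached
    k = ds.length_dispersion
    rho = config.clip_signal
    nodes, weights = np.polynomial.hermite_e.hermegauss(15)
    verb = np.exp(-0.5 * ds.verbosity_sigma**2 + ds.verbosity_sigma * nodes)
    weights = weights / weights.sum()
    pop_means = np.maximum(2.0, ds.length_mean * verb)

    m_grid = np.linspace(2.0, max(6.0 * ds.length_mean, 60.0), 150)
    bg_p = (1.0 - rho) * _zipf_probs(config.global_vocab_size, ds.zipf_exponent)
    pop_bg = sum(w * _phi_nbinom(bg_p, m, k) for w, m in zip(weights, pop_means))
    f = np.array([_phi_nbinom(bg_p, m, k) @ pop_bg for m in m_grid])

    lo, hi = config.clip_zipf_range
    exps = np.linspace(lo, hi, 7)
    topic = np.zeros_like(m_grid)
    for e in exps:
        q = rho * _zipf_probs(config.clip_vocab_size, e)
        pop_t = sum(w * _phi_nbinom(q, m, k) for w, m in zip(weights, pop_means))
        topic += np.array([_phi_nbinom(q, m, k) @ pop_t for m in m_grid])
    out = (m_grid, f + topic / len(exps))
    _CURVE_CACHE[key] = out
    return out


def _free_volumes(
    ds: DatasetConfig, n_clips: int, total: int, rng: np.random.Generator
) -> np.ndarray:
    """Heavy-tailed per-participant response volumes summing to ``total``.

    Lognormal with log-sd ``productivity_sigma``, scaled to the target total
    and capped at one response per clip; at the default sigma the most
    prolific 20% of participants contribute about 60% of the responses.
    """
    raw = rng.lognormal(0.0, ds.productivity_sigma, size=ds.n_participants)
    v = raw * (total / raw.sum())
    vi = np.floor(v).astype(int)
    rem = v - vi
    vi = np.clip(vi, 1, n_clips)
    # largest-remainder repair to the exact total within [1, n_clips]
    order = np.argsort(-rem)
    i = 0
    while vi.sum() < total:
        j = order[i % len(order)]
        if vi[j] < n_clips:
            vi[j] += 1
        i += 1
    order_small = np.argsort(rem)
    i = 0
    while vi.sum() > total:
        j = order_small[i % len(order_small)]
        if vi[j] > 1:
            vi[j] -= 1
        i += 1
    return vi


def _free_assignment(
    volumes: np.ndarray, n_clips: int, rpc: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Assign each participant their volume of distinct clips, filling every
    clip to exactly ``rpc`` responses (most-constrained-clip-first greedy)."""
    capacity = np.full(n_clips, rpc)
    pairs: list[tuple[int, int]] = []
    for p in np.argsort(-volumes):
        v = volumes[p]
        jitter = rng.random(n_clips)
        order = np.lexsort((jitter, -capacity))
        chosen = [c for c in order if capacity[c] > 0][:v]
        if len(chosen) < v:
            raise RuntimeError("infeasible free-mode assignment")
        for c in chosen:
            capacity[c] -= 1
            pairs.append((int(p), int(c)))
    assert capacity.sum() == 0
    return pairs


def _balanced_assignment(
    participants: pd.DataFrame,
    ds: DatasetConfig,
    n_clips: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Each participant sees ``clips_per_participant`` distinct clips; every
    clip is covered equally by each demographic cell (cyclic design)."""
    cpp = ds.clips_per_participant
    cells = participants["cell"].to_numpy()
    n_cells = len(np.unique(cells))
    per_cell = (participants.groupby("cell").size()).iloc[0]
    if ds.responses_per_clip % n_cells:
        raise ValueError(
            "balanced mode needs responses_per_clip divisible by the number "
            f"of demographic cells ({n_cells})"
        )
    if per_cell * cpp != n_clips * (ds.responses_per_clip // n_cells):
        raise ValueError(
            "balanced mode infeasible: participants x clips_per_participant "
            "does not match clips x responses_per_clip"
        )
    if cpp > n_clips:
        raise ValueError("clips_per_participant exceeds the number of clips")
    pairs: list[tuple[int, int]] = []
    for cell in np.unique(cells):
        members = np.flatnonzero(cells == cell)
        rng.shuffle(members)
        offset = int(rng.integers(n_clips))
        for j, p in enumerate(members):
            start = offset + j * cpp
            for t in range(cpp):
                pairs.append((int(p), (start + t) % n_clips))
    return pairs


def generate_responses(
    config: GeneratorConfig,
    participants: dict[str, pd.DataFrame],
    vocabularies: Vocabularies,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Realise the response tables for every dataset in the config.

    Returns the combined responses frame and the per-dataset score slopes
    used to convert score-unit effects to token probabilities.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    all_rows: list[tuple] = []
    slopes: dict[str, float] = {}
    bg_words = np.array(vocabularies.background)
    for ds in config.datasets:
        part = participants[ds.label]
        m_grid, f_grid = length_score_curve(config, ds)
        # words-of-length per unit score at the dataset's typical length
        i0 = int(np.searchsorted(m_grid, ds.length_mean))
        slope = float(
            (f_grid[i0 + 1] - f_grid[i0 - 1]) / (m_grid[i0 + 1] - m_grid[i0 - 1])
        )
        slopes[ds.label] = slope
        total = config.n_clips * ds.responses_per_clip
        if ds.participant_assignment == "balanced":
            pairs = _balanced_assignment(part, ds, config.n_clips, rng)
        elif ds.participant_assignment == "free":
            volumes = _free_volumes(ds, config.n_clips, total, rng)
            pairs = _free_assignment(volumes, config.n_clips, ds.responses_per_clip, rng)
        else:
            raise ValueError(
                f"unknown participant_assignment {ds.participant_assignment!r}"
            )
        bg_cum = np.cumsum(_zipf_probs(config.global_vocab_size, ds.zipf_exponent))
        clip_cums = {
            c: np.cumsum(vocabularies.clip_probs[c]) for c in vocabularies.clip_ids
        }
        clip_arrays = {
            c: np.array(vocabularies.clip_words[c]) for c in vocabularies.clip_ids
        }
        verb = part["verbosity"].to_numpy()
        shift = (part["score_shift"] + part["score_intercept"]).to_numpy()
        lshift = part["length_shift"].to_numpy()
        # invert the expected-score-vs-length curve: each participant's length
        # mean is placed so their expected same-clip score moves by exactly
        # their score-unit shift, on top of any direct length effects
        natural_m = np.maximum(2.0, ds.length_mean * verb + lshift)
        target = np.interp(natural_m, m_grid, f_grid) + shift
        m_final = np.interp(target, f_grid, m_grid)
        # the inversion is convex, which would drift the dataset mean length
        # upward; recentre with a constant offset (leaves score contrasts
        # between participants intact)
        m_final = np.maximum(2.0, m_final + (natural_m.mean() - m_final.mean()))
        pid = part["participant_id"].to_numpy()
        k = ds.length_dispersion
        sw_odds = config.stopword_rate / (1.0 - config.stopword_rate)
        for i, (p, c) in enumerate(pairs):
            clip_id = vocabularies.clip_ids[c]
            rho = vocabularies.clip_rho[clip_id]
            m = m_final[p]
            length = int(rng.negative_binomial(k, k / (k + m)))
            n_topic = int(rng.binomial(length, rho)) if length else 0
            t_idx = np.searchsorted(clip_cums[clip_id], rng.random(n_topic))
            topic_words = clip_arrays[clip_id][
                np.minimum(t_idx, config.clip_vocab_size - 1)
            ]
            n_bg = length - n_topic
            b_idx = np.searchsorted(bg_cum, rng.random(n_bg))
            bgs = bg_words[np.minimum(b_idx, config.global_vocab_size - 1)]
            tokens = np.concatenate([topic_words, bgs])
            rng.shuffle(tokens)
            n_stop = int(rng.poisson(length * sw_odds)) if length else 1
            stops = _FILLERS[rng.integers(0, len(_FILLERS), size=n_stop)]
            raw = np.concatenate([tokens, stops])
            rng.shuffle(raw)
            cut = int(round(len(raw) * config.prompt_split))
            all_rows.append(
                (
                    f"{ds.label[:4]}r{i:05d}",
                    pid[p],
                    clip_id,
                    ds.label,
                    " ".join(raw[:cut]),
                    " ".join(raw[cut:]),
                )
            )
    responses = pd.DataFrame(
        all_rows,
        columns=["response_id", "participant_id", "clip_id", "dataset", "prompt_a", "prompt_b"],
    )
    return responses, slopes


def generate_study(
    config: GeneratorConfig | None = None, out_dir: str | Path | None = None
) -> StudyBundle:
    """Generate a full synthetic study; optionally write it to ``out_dir``.

    The default configuration produces the study shape the pipeline targets:
    200 clips, 4000 crowdsourced responses (99 free-volume workers) and 2400
    lab responses (60 participants, 40 clips each), with dataset mean content
    lengths 33 and 28.  Fully reproducible from ``config.seed``.
    """
    config = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    vocabs = generate_vocabularies(config, rng)
    participants = {
        ds.label: generate_participants(config, ds, rng) for ds in config.datasets
    }
    responses, slopes = generate_responses(config, participants, vocabs, rng)
    part_all = pd.concat(participants.values(), ignore_index=True)
    truth = TruthRecord(
        seed=config.seed,
        config=dataclasses.asdict(config),
        clip_exponents=vocabs.clip_exponents,
        clip_rho=vocabs.clip_rho,
        score_slopes=slopes,
        clip_words={c: list(w) for c, w in vocabs.clip_words.items()},
    )
    bundle = StudyBundle(responses=responses, participants=part_all, truth=truth)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
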