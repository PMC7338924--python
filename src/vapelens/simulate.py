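"""Synthetic corpus and entry generators.

Multi-million-post forum dumps of the kind this analysis targets are not
redistributable, so every stage of this package is exercised against a
generated corpus with the statistical structure the analysis assumes:
user-clustered posts, a monthly volume trend, configurable flavor
frequencies, health-category co-mention probabilities conditional on
flavor, within-user correlation through a logit-normal random intercept,
and sentiment-valenced post templates.

Ground truth accessors (:func:`conditional_comention`,
:func:`marginal_comention_matrix`) expose exactly what was planted: the
marginal matrix integrates the user perturbation out numerically and
equals the configured matrix when ``user_effect_sd`` is 0. A
population-averaged (GEE) estimate targets that marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import AssociationEntry
from .taxonomy import (
    DisambiguationRule,
    KeywordTaxonomy,
    Post,
)

__all__ = [
    "SimulationConfig",
    "fixture_taxonomies",
    "generate_corpus",
    "generate_entries",
    "conditional_comention",
    "marginal_comention_matrix",
]

ECIG_TERMS = [
    "e-cig", "e-cigs", "ecig", "ecigs", "electroniccigarette", "ecigarette",
    "ecigarettes", "vape", "vapers", "vaping", "vapes", "e-liquid", "ejuice",
    "eliquid", "e-juice", "vapercon", "vapeon", "vapefam", "vapenation",
    "juul",
]

TOBACCO_CONTEXT = [
    "flavor", "flavour", "flavored", "flavoured", "e-liquid", "eliquid",
    "ejuice", "e-juice", "juice", "vape",
]

_HEALTH_KEYWORDS = {
    "Respiratory": ["cough", "coughing", "wheezing", "asthma", "shortness of breath"],
    "Cardiovascular": ["palpitations", "chest pain", "high blood pressure",
                       "heart attack", "stroke"],
    "Neurological": ["headache", "migraine", "dizziness", "dizzy", "seizure"],
    "Psychological": ["anxiety", "depression", "panic attack", "insomnia",
                      "mood swings"],
    "Digestive": ["nausea", "vomiting", "diarrhea", "stomach ache", "heartburn"],
    "Mouth": ["dry mouth", "mouth sores", "gum bleeding", "bad breath",
              "tooth pain"],
    "Throat": ["sore throat", "throat irritation", "hoarseness",
               "scratchy throat", "dry throat"],
    "Cancer": ["cancer", "tumor", "carcinoma", "lung cancer", "leukemia"],
    "Other": ["fatigue", "rash", "fever", "chills", "sweating"],
}

_FLAVOR_KEYWORDS = {
    "Fruit": ["strawberry", "mango", "watermelon", "blueberry", "apple"],
    "Menthol or Mint": ["menthol", "mint", "peppermint", "spearmint", "icy"],
    "Tobacco": ["tobacco", "cuban blend", "ry4"],
    "Sweet": ["custard", "caramel", "candy", "vanilla", "honey"],
    "Beverage": ["coffee", "cola", "lemonade", "mojito", "espresso"],
    "Mixed": ["fruit medley", "tropical blend", "berry mix", "mixed berry",
              "fusion"],
    "Other": ["cinnamon", "clove", "floral", "rose", "unflavored"],
}

HEALTH_COLUMNS = (
    "Respiratory", "Cardiovascular", "Neurological", "Psychological",
    "Digestive", "Throat", "Mouth", "Cancer",
)
FLAVOR_ROWS = ("Fruit", "Menthol or Mint", "Tobacco", "Sweet", "Beverage", "Mixed")

# Conditional co-mention matrix P(health | flavor, any health mention).
# Cells shown in the source heatmap/prose are anchored (e.g. Menthol-
# Respiratory 0.200, Menthol-Throat 0.344, Sweet-Throat 0.301,
# Beverage-Throat 0.279, Fruit-Cardiovascular 0.080, Mixed-Psychological
# 0.106); Mouth absorbs the undisplayed remainder and Cancer stays rare.
# Rows sum to 1 over the eight modeled health categories.
DEFAULT_CONDITIONAL = pd.DataFrame(
    [
        [0.160, 0.080, 0.079, 0.095, 0.066, 0.250, 0.250, 0.020],
        [0.200, 0.045, 0.060, 0.070, 0.055, 0.344, 0.206, 0.020],
        [0.197, 0.060, 0.050, 0.065, 0.045, 0.230, 0.328, 0.025],
        [0.169, 0.050, 0.070, 0.080, 0.085, 0.301, 0.225, 0.020],
        [0.120, 0.055, 0.065, 0.075, 0.070, 0.279, 0.316, 0.020],
        [0.169, 0.055, 0.086, 0.106, 0.060, 0.220, 0.284, 0.020],
    ],
    index=list(FLAVOR_ROWS),
    columns=list(HEALTH_COLUMNS),
)

DEFAULT_FLAVOR_DISTRIBUTION = {
    "Fruit": 0.20,
    "Menthol or Mint": 0.12,
    "Tobacco": 0.08,
    "Sweet": 0.15,
    "Beverage": 0.08,
    "Mixed": 0.12,
    # remaining 0.25: no flavor mention
}

_POS_HEALTH = [
    "My {health} is so much better since switching and I love it.",
    "Happy to report the {health} improved, this is great.",
    "Even with a mild {health} I enjoy it, best decision ever.",
]
_NEG_HEALTH = [
    "It gave me a terrible {health} and I feel awful.",
    "Got a nasty {health} again, this is horrible.",
    "The {health} is worse every week and I regret it.",
]
_NEU_HEALTH = [
    "I noticed a {health} this week.",
    "Had a {health} on Tuesday after the gym.",
    "Someone else mentioned a {health} in another thread.",
]
_POS_PLAIN = [
    "Tastes great and I love it.",
    "This setup is awesome, best purchase this year.",
    "Really happy with the smooth draw.",
]
_NEG_PLAIN = [
    "The coil burned out and it tastes awful.",
    "Customer service was horrible and I regret ordering.",
    "The battery is bad and the leak is nasty.",
]
_NEU_PLAIN = [
    "I ordered another bottle yesterday.",
    "Picked up new coils at the shop.",
    "Still deciding which nicotine strength to reorder.",
]


def fixture_taxonomies() -> tuple[KeywordTaxonomy, KeywordTaxonomy, KeywordTaxonomy]:
    """(ecig, health, flavor) fixture taxonomies, validated.

    A deliberately small stand-in (about five keywords per category) for
    the study-scale lists; the tobacco keyword carries the ten-term
    sentence-context disambiguation rule.
    """
    ecig = KeywordTaxonomy("ecig", {"ecig": list(ECIG_TERMS)}).validate()
    health = KeywordTaxonomy(
        "health", {c: list(v) for c, v in _HEALTH_KEYWORDS.items()}
    ).validate()
    flavor = KeywordTaxonomy(
        "flavor",
        {c: list(v) for c, v in _FLAVOR_KEYWORDS.items()},
        disambiguation_rules=[
            DisambiguationRule("tobacco", tuple(TOBACCO_CONTEXT))
        ],
    ).validate()
    return ecig, health, flavor


@dataclass
class SimulationConfig:
    """The stated world of the generator; all probabilities are inputs.

    ``comention_matrix`` rows are P(health category | flavor category)
    per *corpus post*; row sums may be below 1, the remainder being the
    probability of no health mention. ``user_effect_sd`` is the standard
    deviation of per-user logit-scale random effects: a scalar intercept
    on the any-health propensity and one effect per health category on
    the conditional row (renormalized), so users are idiosyncratically
    prone to particular symptoms and their entries are positively
    correlated within category.
    """

    n_users: int = 500
    posts_per_user_mean: float = 4.0
    date_range: tuple[str, str] = ("2013-01", "2019-04")
    monthly_volume_trend: Sequence[float] | None = None  # multiplier per month
    flavor_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLAVOR_DISTRIBUTION)
    )
    comention_matrix: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_CONDITIONAL * 0.5
    )
    background_health_rate: float = 0.3
    user_effect_sd: float = 0.5
    sentiment_mix: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            **{c: (0.55, 0.15, 0.30) for c in HEALTH_COLUMNS},
            "Other": (0.55, 0.15, 0.30),
            "Cancer": (0.15, 0.10, 0.75),
            "__none__": (0.60, 0.20, 0.20),
        }
    )
    entries_per_user: int = 3
    contamination_rate: float = 0.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        if self.user_effect_sd < 0:
            raise ValueError("user_effect_sd must be >= 0")
        fsum = sum(self.flavor_distribution.values())
        if not (0 < fsum <= 1 + 1e-9) or any(
            p < 0 for p in self.flavor_distribution.values()
        ):
            raise ValueError("flavor_distribution must be a sub-probability vector")
        rows = self.comention_matrix.sum(axis=1)
        if (self.comention_matrix.values < 0).any() or (rows > 1 + 1e-9).any():
            raise ValueError("comention_matrix rows must be sub-probability vectors")
        for mix in self.sentiment_mix.values():
            if abs(sum(mix) - 1) > 1e-9 or any(p < 0 for p in mix):
                raise ValueError("sentiment_mix rows must sum to 1")
        return self


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p) - np.log1p(-np.asarray(p, dtype=float))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def conditional_comention(config: SimulationConfig) -> pd.DataFrame:
    """P(health | flavor, co-mention): the comention matrix with rows
    renormalized to 1. This is the matrix entries are drawn from."""
    m = config.comention_matrix
    return m.div(m.sum(axis=1), axis=0)


def _perturbed_row(row: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-user conditional category row: logit-shift each cell by the
    user's category effect vector, then renormalize.

    The effect is per category (one N(0, sd) draw per health category
    per user), modeling users idiosyncratically prone to particular
    symptoms; a shift common to all categories would cancel in the
    renormalization and induce no within-user correlation.
    """
    q = _invlogit(_logit(row) + b)
    return q / q.sum()


_MARGINAL_MC_SEED = 20130101  # fixed: numerical integration, not simulation
_MARGINAL_MC_DRAWS = 400_000


def marginal_comention_matrix(
    config: SimulationConfig, n_draws: int = _MARGINAL_MC_DRAWS
) -> pd.DataFrame:
    """Population-averaged conditional co-mention matrix.

    Integrates the per-user renormalized rows over the N(0, sd^2)
    category-effect vector by seeded Monte Carlo (the integral is
    8-dimensional, out of quadrature's reach); the Monte Carlo error at
    the default draw count is below 5e-4 per cell. Equals
    :func:`conditional_comention` exactly when ``user_effect_sd`` is 0.
    """
    cond = conditional_comention(config)
    sd = config.user_effect_sd
    if sd == 0.0:
        return cond.copy()
    rng = np.random.default_rng(_MARGINAL_MC_SEED)
    k = cond.shape[1]
    b = rng.normal(0.0, sd, size=(n_draws, k))
    out = np.zeros_like(cond.values)
    for i, row in enumerate(cond.values):
        q = _invlogit(_logit(row)[None, :] + b)
        q = q / q.sum(axis=1, keepdims=True)
        out[i] = q.mean(axis=0)
    return pd.DataFrame(out, index=cond.index, columns=cond.columns)


def _month_weights(config: SimulationConfig) -> tuple[pd.PeriodIndex, np.ndarray]:
    months = pd.period_range(config.date_range[0], config.date_range[1], freq="M")
    if config.monthly_volume_trend is not None:
        w = np.asarray(config.monthly_volume_trend, dtype=float)
        if len(w) != len(months):
            raise ValueError(
                f"monthly_volume_trend needs {len(months)} entries, got {len(w)}"
            )
    else:
        w = np.linspace(1.0, 2.0, len(months))  # gentle volume growth
    return months, w / w.sum()


def _draw_timestamp(rng: np.random.Generator, month: pd.Period) -> int:
    start = month.to_timestamp(how="start").timestamp()
    end = month.to_timestamp(how="end").timestamp()
    return int(rng.uniform(start, end))


def _draw_polarity(rng, mix: tuple[float, float, float]) -> str:
    return ("positive", "neutral", "negative")[
        rng.choice(3, p=np.asarray(mix) / sum(mix))
    ]


def _sentiment_sentence(rng, polarity: str, health_kw: str | None) -> str:
    bank = {
        ("positive", True): _POS_HEALTH, ("negative", True): _NEG_HEALTH,
        ("neutral", True): _NEU_HEALTH, ("positive", False): _POS_PLAIN,
        ("negative", False): _NEG_PLAIN, ("neutral", False): _NEU_PLAIN,
    }[(polarity, health_kw is not None)]
    tpl = bank[rng.integers(0, len(bank))]
    return tpl.format(health=health_kw) if health_kw is not None else tpl


def generate_corpus(config: SimulationConfig) -> list[Post]:
    """User-clustered synthetic posts; deterministic for a given seed.

    Each post embeds an e-cigarette term, at most one flavor keyword by
    construction (sentence-templated so the tobacco context rule passes),
    optionally one health keyword drawn from the user-perturbed
    co-mention row, and a sentiment-valenced sentence. The optional
    ``contamination_rate`` injects a second, different-category flavor
    keyword to exercise the single-flavor exclusion rule downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    months, month_w = _month_weights(config)
    flavor_cats = list(config.flavor_distribution)
    flavor_p = np.array([config.flavor_distribution[c] for c in flavor_cats])
    p_none = 1.0 - flavor_p.sum()
    cats_with_none = flavor_cats + ["__none__"]
    draw_p = np.append(flavor_p, max(p_none, 0.0))
    draw_p = draw_p / draw_p.sum()
    cond = conditional_comention(config)
    any_rate = config.comention_matrix.sum(axis=1)
    health_cols = list(cond.columns)

    posts: list[Post] = []
    pid = 0
    for ui in range(config.n_users):
        user_id = f"u{ui:05d}"
        if config.user_effect_sd:
            b_any = rng.normal(0.0, config.user_effect_sd)
            b_cat = rng.normal(0.0, config.user_effect_sd, size=len(health_cols))
        else:
            b_any, b_cat = 0.0, None
        n_posts = rng.poisson(config.posts_per_user_mean)
        for _ in range(n_posts):
            month = months[rng.choice(len(months), p=month_w)]
            ts = _draw_timestamp(rng, month)
            flavor_cat = cats_with_none[rng.choice(len(cats_with_none), p=draw_p)]

            health_cat: str | None = None
            if flavor_cat != "__none__" and flavor_cat in cond.index:
                p_any = float(any_rate.loc[flavor_cat])
                if config.user_effect_sd:
                    p_any = float(_invlogit(_logit(p_any) + b_any))
                if rng.random() < p_any:
                    row = cond.loc[flavor_cat].to_numpy()
                    if b_cat is not None:
                        row = _perturbed_row(row, b_cat)
                    health_cat = health_cols[rng.choice(len(health_cols), p=row)]
            elif rng.random() < config.background_health_rate:
                health_cat = health_cols[rng.integers(0, len(health_cols))]

            ecig_term = ECIG_TERMS[rng.integers(0, len(ECIG_TERMS))]
            sentences = []
            if flavor_cat != "__none__":
                kws = _FLAVOR_KEYWORDS[flavor_cat]
                fkw = kws[rng.integers(0, len(kws))]
                sentences.append(
                    f"Just tried the {fkw} flavor e-liquid in my {ecig_term}."
                )
            else:
                sentences.append(f"Been using my {ecig_term} all week.")

            health_kw = None
            if health_cat is not None:
                hkws = _HEALTH_KEYWORDS[health_cat]
                health_kw = hkws[rng.integers(0, len(hkws))]
            mix = config.sentiment_mix.get(
                health_cat if health_cat is not None else "__none__",
                (0.34, 0.33, 0.33),
            )
            polarity = _draw_polarity(rng, mix)
            sentences.append(_sentiment_sentence(rng, polarity, health_kw))

            if (
                config.contamination_rate
                and flavor_cat != "__none__"
                and rng.random() < config.contamination_rate
            ):
                other_cats = [c for c in flavor_cats if c != flavor_cat]
                oc = other_cats[rng.integers(0, len(other_cats))]
                okw = _FLAVOR_KEYWORDS[oc][0]
                sentences.append(f"I also vape {okw} flavor sometimes.")

            posts.append(
                Post(f"p{pid:07d}", user_id, ts, " ".join(sentences))
            )
            pid += 1
    return posts


def generate_entries(config: SimulationConfig) -> list[AssociationEntry]:
    """Directly emit user-clustered association entries, bypassing text.

    Each user contributes ``entries_per_user`` entries; flavors are drawn
    from the (renormalized) flavor distribution and health categories
    from the user-perturbed conditional co-mention row — the same
    construction the corpus generator uses, so corpus-derived and direct
    entries share their marginals.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cond = conditional_comention(config)
    flavor_cats = [c for c in config.flavor_distribution if c in cond.index]
    fp = np.array([config.flavor_distribution[c] for c in flavor_cats])
    fcum = np.cumsum(fp / fp.sum())
    health_cols = list(cond.columns)
    base = cond.loc[flavor_cats].to_numpy()
    base_logit = _logit(base)

    entries: list[AssociationEntry] = []
    pid = 0
    n = config.entries_per_user
    for ui in range(config.n_users):
        user_id = f"u{ui:05d}"
        if config.user_effect_sd:
            b_cat = rng.normal(0.0, config.user_effect_sd, size=base.shape[1])
            rows = _invlogit(base_logit + b_cat)
            rows = np.cumsum(rows / rows.sum(axis=1, keepdims=True), axis=1)
        else:
            rows = np.cumsum(base, axis=1)
        u = rng.random((n, 2))
        f_idx = np.searchsorted(fcum, u[:, 0])
        for j in range(n):
            fi = min(int(f_idx[j]), len(flavor_cats) - 1)
            hi = min(
                int(np.searchsorted(rows[fi], u[j, 1])), len(health_cols) - 1
            )
            entries.append(
                AssociationEntry(
                    user_id, f"e{pid:07d}", flavor_cats[fi], health_cols[hi]
                )
            )
            pid += 1
    return entries
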