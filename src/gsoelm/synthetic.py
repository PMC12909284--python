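"""Synthetic screening-style tabular data.

Emulates the schema of public toddler autism screening tables: ten binary
questionnaire items summed into a 0-10 QCHAT-style score, age in months,
and demographic columns (sex, ethnicity, neonatal jaundice, family history,
test completer), with controllable class balance, class-conditional item
rates, weak demographic signal, MCAR missingness and label noise.  Also
ships the 20-row sample table printed in the source literature as a fixture
(``sample_table_fixture``), and a generic planted-signal Gaussian generator for
feature-selection recovery experiments.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import ColumnSpec, RawSchema

logger = logging.getLogger("gsoelm.synthetic")

ETHNICITIES = ("Asian", "Black", "Hispanic", "Middle Eastern", "South Asian",
               "White European")
COMPLETERS = ("Family member", "Healthcare professional")

#: Role declarations for the standard toddler screening-table layout.
TODDLER_SCHEMA = RawSchema([
    ColumnSpec("Age_Mons", "numeric"),
    ColumnSpec("Qchat_10_Score", "numeric"),
    ColumnSpec("Sex", "categorical"),
    ColumnSpec("Ethnicity", "categorical"),
    ColumnSpec("Jaundice", "categorical"),
    ColumnSpec("Family_ASD", "categorical"),
    ColumnSpec("Who_completed", "categorical"),
    ColumnSpec("Class", "label"),
])

# The 20 sample rows as printed (age months, QCHAT score, sex, ethnicity,
# jaundice, family ASD history, test completer, class).
_SAMPLE_TABLE_CSV = """\
Age_Mons,Qchat_10_Score,Sex,Ethnicity,Jaundice,Family_ASD,Who_completed,Class
28,3,f,Middle Eastern,Yes,No,Family member,No
36,4,m,White European,Yes,No,Family member,Yes
36,4,m,Middle Eastern,Yes,No,Family member,Yes
24,10,m,Hispanic,No,No,Family member,Yes
20,9,f,White European,No,Yes,Family member,Yes
21,8,m,Black,No,No,Family member,Yes
33,5,m,Asian,Yes,No,Family member,Yes
33,6,m,Asian,Yes,No,Family member,Yes
36,2,m,Asian,No,No,Family member,No
22,8,m,South Asian,No,No,Healthcare professional,Yes
36,6,m,Hispanic,Yes,Yes,Family member,Yes
17,8,m,Middle Eastern,Yes,No,Family member,Yes
25,0,f,Middle Eastern,Yes,No,Family member,No
15,7,f,Middle Eastern,Yes,No,Family member,Yes
18,0,m,Middle Eastern,No,No,Family member,No
12,7,m,Black,No,No,Family member,Yes
36,0,m,Middle Eastern,No,Yes,Family member,No
12,8,f,Middle Eastern,Yes,No,Family member,Yes
29,3,f,Middle Eastern,No,No,Family member,No
12,7,f,Black,No,No,Family member,Yes
"""


def sample_table_fixture() -> pd.DataFrame:
    """The 20-row printed sample table, exactly as published."""
    return pd.read_csv(io.StringIO(_SAMPLE_TABLE_CSV), dtype={"Age_Mons": int, "Qchat_10_Score": int})


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the screening-data generator.

    The defaults mirror a majority-positive mobile screening sample:
    positive rate 0.69, ten binary items answered "concerning" with
    probability 0.7 in the positive class and 0.15 in the negative class,
    and demographics with a mild class-dependent odds shift on jaundice and
    family history (odds multiplier 1.5) so they carry weak signal.
    ``score_threshold`` is the conventional QCHAT-10 cut-off; when
    ``threshold_labels`` is set the class is re-derived as score >=
    threshold instead of the latent Bernoulli draw.
    """

    n: int = 500
    positive_rate: float = 0.69
    item_count: int = 10
    item_rate_positive: float = 0.7
    item_rate_negative: float = 0.15
    score_threshold: int = 4
    threshold_labels: bool = False
    sex_female_rate: float = 0.5
    ethnicity_probs: dict[str, float] = field(default_factory=lambda: {
        "Middle Eastern": 0.30, "White European": 0.20, "Asian": 0.15,
        "Black": 0.15, "Hispanic": 0.10, "South Asian": 0.10,
    })
    jaundice_rate: float = 0.30
    family_history_rate: float = 0.15
    completer_family_rate: float = 0.90
    class_odds_multiplier: float = 1.5
    missing_rate: float = 0.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        for name in ("positive_rate", "item_rate_positive", "item_rate_negative",
                     "sex_female_rate", "jaundice_rate", "family_history_rate",
                     "completer_family_rate"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must lie strictly in (0, 1)")
        if not 0 <= self.missing_rate <= 0.3:
            raise ValueError("missing_rate must lie in [0, 0.3]")
        if not 0 <= self.label_noise <= 0.3:
            raise ValueError("label_noise must lie in [0, 0.3]")
        total = sum(self.ethnicity_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("ethnicity probabilities must sum to 1")


@dataclass
class SyntheticDataset:
    """Generated table plus the generating ground truth."""

    table: pd.DataFrame
    true_class: np.ndarray          # class before label-noise flips
    items: np.ndarray               # n x item_count binary item responses
    informative_columns: list[str]  # raw columns carrying class signal
    schema: RawSchema


def _shift_rate(base: float, positive: np.ndarray, multiplier: float) -> np.ndarray:
    """Per-row Bernoulli rate with class-dependent odds shift for positives."""
    odds = base / (1.0 - base)
    p_pos = (odds * multiplier) / (1.0 + odds * multiplier)
    return np.where(positive, p_pos, base)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a screening-style dataset under the configured study conditions.

    Class is Bernoulli(positive_rate); items are class-conditional
    Bernoullis whose sum is the QCHAT score; age is uniform on 12-36
    months; label noise flips each label independently; missingness is MCAR
    over feature cells only.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    true_class = (rng.random(n) < config.positive_rate).astype(int)
    pos = true_class == 1

    rates = np.where(pos[:, None], config.item_rate_positive, config.item_rate_negative)
    items = (rng.random((n, config.item_count)) < rates).astype(int)
    score = items.sum(axis=1)
    if config.threshold_labels:
        true_class = (score >= config.score_threshold).astype(int)
        pos = true_class == 1

    age = rng.integers(12, 37, size=n)
    sex = np.where(rng.random(n) < config.sex_female_rate, "f", "m")
    eths = list(config.ethnicity_probs)
    eth = rng.choice(eths, size=n, p=[config.ethnicity_probs[e] for e in eths])
    jaundice = np.where(
        rng.random(n) < _shift_rate(config.jaundice_rate, pos, config.class_odds_multiplier),
        "Yes", "No")
    family = np.where(
        rng.random(n) < _shift_rate(config.family_history_rate, pos, config.class_odds_multiplier),
        "Yes", "No")
    completer = np.where(rng.random(n) < config.completer_family_rate,
                         COMPLETERS[0], COMPLETERS[1])

    label = true_class.copy()
    if config.label_noise > 0:
        flips = rng.random(n) < config.label_noise
        label = np.where(flips, 1 - label, label)

    table = pd.DataFrame({
        "Age_Mons": age,
        "Qchat_10_Score": score,
        "Sex": sex,
        "Ethnicity": eth,
        "Jaundice": jaundice,
        "Family_ASD": family,
        "Who_completed": completer,
        "Class": np.where(label == 1, "Yes", "No"),
    })

    if config.missing_rate > 0:
        feature_cols = [c.name for c in TODDLER_SCHEMA.feature_columns]
        holes = rng.random((n, len(feature_cols))) < config.missing_rate
        table = table.astype({c: object for c in feature_cols})
        for j, col in enumerate(feature_cols):
            table.loc[holes[:, j], col] = None

    return SyntheticDataset(
        table=table, true_class=true_class, items=items,
        informative_columns=["Qchat_10_Score", "Jaundice", "Family_ASD"],
        schema=TODDLER_SCHEMA,
    )


def generate_planted(
    n: int = 300,
    n_features: int = 20,
    n_informative: int = 5,
    effect_size: float = 1.0,
    positive_rate: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian design with a known informative-column subset.

    The first ``n_informative`` columns get a class-dependent mean shift of
    ``effect_size``; the rest are pure noise.  Returns (X, y,
    informative_mask) for parameter-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < positive_rate).astype(int)
    X = rng.standard_normal((n, n_features))
    X[:, :n_informative] += effect_size * y[:, None]
    informative = np.zeros(n_features, dtype=bool)
    informative[:n_informative] = True
    return X, y, informative


def noise_inject(X: np.ndarray, noise_level: float, seed: int = 0) -> np.ndarray:
    """Perturb a numeric design matrix by a given noise level.

    Binary {0,1} columns are flipped with probability ``noise_level``;
    other numeric columns get additive uniform noise of half-width
    noise_level times the column range.
    """
    if not 0 <= noise_level <= 0.5:
        raise ValueError("noise_level must lie in [0, 0.5]")
    X = np.asarray(X, dtype=float)
    out = X.copy()
    if noise_level == 0:
        return out
    rng = np.random.default_rng(seed)
    for j in range(X.shape[1]):
        col = X[:, j]
        values = np.unique(col)
        if np.all(np.isin(values, (0.0, 1.0))):
            flips = rng.random(len(col)) < noise_level
            out[:, j] = np.where(flips, 1.0 - col, col)
        else:
            span = col.max() - col.min()
            out[:, j] = col + rng.uniform(-noise_level * span, noise_level * span, len(col))
    return out
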