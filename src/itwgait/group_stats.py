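"""3 (foot model) x 2 (walking condition) within-subject factorial analysis.

Each clinical parameter yields one complete-case table: one row per
subject, six cells (OFM/PiG/DAV x BF/FO).  The analysis is a two-way
repeated-measures ANOVA with each effect tested against its own
effect-by-subject interaction; effect size is partial eta squared
(classical eta squared available by switch).  When any cell fails a
Shapiro-Wilk normality check the pipeline routes to the aligned rank
transform (ART): per effect, subtract the contributions of all other
effects estimated from cell/marginal means, rank with midranks, run the
same parametric ANOVA on the ranks and keep only that effect's line.
Post-hoc comparisons are paired t-tests with Bonferroni adjustment
(families: 3 model pairs, alpha_adj ~ 0.0167; 1 condition pair per model,
alpha 0.05).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gaitdata_io import Condition, FootModel, GaitDataError

__all__ = [
    "MODEL_ORDER",
    "CONDITION_ORDER",
    "CohortTable",
    "EffectResult",
    "PosthocResult",
    "PosthocFamily",
    "FactorialReport",
    "shapiro_normality",
    "rm_anova_3x2",
    "art_anova_3x2",
    "bonferroni_posthoc",
    "run_factorial_pipeline",
]

MODEL_ORDER: tuple[FootModel, ...] = (FootModel.OFM, FootModel.PIG, FootModel.DAV)
CONDITION_ORDER: tuple[Condition, ...] = (Condition.BF, Condition.FO)

ALPHA = 0.05


class CohortTable:
    """Complete-case subject x model x condition values for one parameter.

    Constructed from a tidy frame with columns
    ``subject, model, condition, value``; every subject must contribute all
    six cells exactly once.
    """

    def __init__(self, data: pd.DataFrame, parameter: str = "") -> None:
        required = {"subject", "model", "condition", "value"}
        if not required.issubset(data.columns):
            raise GaitDataError(f"cohort table needs columns {sorted(required)}")
        df = data.copy()
        df["model"] = df["model"].map(lambda m: FootModel(m).value)
        df["condition"] = df["condition"].map(lambda c: Condition(c).value)
        counts = df.groupby("subject").size()
        if (counts != 6).any() or df.duplicated(
            ["subject", "model", "condition"]
        ).any():
            raise GaitDataError("cohort table must be complete-case: 6 cells/subject")
        if counts.size < 2:
            raise GaitDataError("cohort table needs at least 2 subjects")
        self.data = df
        self.parameter = parameter
        self.subjects = sorted(df["subject"].unique())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def wide(self) -> np.ndarray:
        """Values as an (n_subjects, 3 models, 2 conditions) array."""
        out = np.empty((self.n_subjects, len(MODEL_ORDER), len(CONDITION_ORDER)))
        idx = {
            (r.subject, r.model, r.condition): r.value
            for r in self.data.itertuples()
        }
        for s, subj in enumerate(self.subjects):
            for i, m in enumerate(MODEL_ORDER):
                for j, c in enumerate(CONDITION_ORDER):
                    out[s, i, j] = idx[(subj, m.value, c.value)]
        return out

    @classmethod
    def from_wide(cls, values: np.ndarray, parameter: str = "") -> "CohortTable":
        values = np.asarray(values, dtype=float)
        rows = []
        for s in range(values.shape[0]):
            for i, m in enumerate(MODEL_ORDER):
                for j, c in enumerate(CONDITION_ORDER):
                    rows.append((f"S{s:02d}", m.value, c.value, values[s, i, j]))
        return cls(
            pd.DataFrame(rows, columns=["subject", "model", "condition", "value"]),
            parameter=parameter,
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, parameter: str = "") -> "CohortTable":
        return cls(pd.read_csv(path), parameter=parameter)


@dataclass
class EffectResult:
    """One line of the factorial ANOVA."""

    effect: str              # "model" | "condition" | "interaction"
    F: float
    df: tuple[int, int]
    p: float
    eta2: float
    undefined: bool = False  # zero error sum of squares

    @property
    def significant(self) -> bool:
        return (not self.undefined) and self.p < ALPHA


@dataclass
class PosthocResult:
    comparison: str
    mean_diff: float
    p_adjusted: float
    significant: bool
    alpha_adjusted: float


class PosthocFamily(str, Enum):
    MODELS_WITHIN_CONDITION = "models_within_condition"
    CONDITIONS_WITHIN_MODEL = "conditions_within_model"
    MODELS_POOLED = "models_pooled"
    CONDITIONS_POOLED = "conditions_pooled"


def shapiro_normality(table: CohortTable) -> dict[tuple[str, str], float]:
    """Shapiro-Wilk p-value of the residuals of each of the six cells.

    Residuals are the cell values minus the cell mean.  Zero-variance cells
    are flagged non-normal (p = 0), which routes the pipeline to ART.
    """
    Y = table.wide()
    if Y.shape[0] < 3:
        raise GaitDataError("normality check needs cell n >= 3")
    out: dict[tuple[str, str], float] = {}
    for i, m in enumerate(MODEL_ORDER):
        for j, c in enumerate(CONDITION_ORDER):
            cell = Y[:, i, j]
            resid = cell - cell.mean()
            if np.allclose(resid, 0.0):
                out[(m.value, c.value)] = 0.0
            else:
                out[(m.value, c.value)] = float(stats.shapiro(resid).pvalue)
    return out


def _anova_from_wide(Y: np.ndarray, classical_eta2: bool = False) -> list[EffectResult]:
    n, a, b = Y.shape
    if n < 2:
        raise GaitDataError("repeated-measures ANOVA needs n >= 2 subjects")
    gm = Y.mean()
    subj = Y.mean(axis=(1, 2))            # per-subject means
    A = Y.mean(axis=(0, 2))               # model marginal means
    B = Y.mean(axis=(0, 1))               # condition marginal means
    M = Y.mean(axis=0)                    # cell means (a, b)
    SA = Y.mean(axis=2)                   # subject x model means (n, a)
    SB = Y.mean(axis=1)                   # subject x condition means (n, b)

    ss_a = n * b * np.sum((A - gm) ** 2)
    ss_as = b * np.sum((SA - A[None, :] - subj[:, None] + gm) ** 2)
    ss_b = n * a * np.sum((B - gm) ** 2)
    ss_bs = a * np.sum((SB - B[None, :] - subj[:, None] + gm) ** 2)
    ss_ab = n * np.sum((M - A[:, None] - B[None, :] + gm) ** 2)
    resid = (
        Y
        - SA[:, :, None]
        - SB[:, None, :]
        - M[None, :, :]
        + A[None, :, None]
        + B[None, None, :]
        + subj[:, None, None]
        - gm
    )
    ss_abs = np.sum(resid**2)
    ss_total = np.sum((Y - gm) ** 2)

    # sums of squares this small (relative to the data) are rounding noise
    tol = 1e-12 * max(ss_total, 1e-30)
    rows = []
    for effect, ss_e, df_e, ss_err, df_err in (
        ("model", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        ("condition", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        ("interaction", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ):
        if ss_err <= tol:
            if ss_e <= tol:  # no effect and no error: report a null effect
                rows.append(EffectResult(effect, 0.0, (df_e, df_err), 1.0, 0.0))
            else:  # real effect against a zero error term: F undefined
                rows.append(EffectResult(effect, float("nan"), (df_e, df_err),
                                         float("nan"), float("nan"),
                                         undefined=True))
            continue
        F = (ss_e / df_e) / (ss_err / df_err)
        p = float(stats.f.sf(F, df_e, df_err))
        denom = ss_total if classical_eta2 else (ss_e + ss_err)
        eta2 = float(ss_e / denom) if denom > 0 else float("nan")
        rows.append(EffectResult(effect, float(F), (df_e, df_err), p, eta2))
    return rows


def rm_anova_3x2(
    table: CohortTable, classical_eta2: bool = False
) -> list[EffectResult]:
    """Two-way repeated-measures ANOVA of a 3 x 2 complete-case table.

    Within-subject sums of squares are partitioned into model, condition
    and interaction effects, each tested against its own effect-by-subject
    error term (df for n = 14: model and interaction (2, 26), condition
    (1, 13)).  Effect size defaults to partial eta squared,
    SS_effect / (SS_effect + SS_error).
    """
    return _anova_from_wide(table.wide(), classical_eta2=classical_eta2)


def art_anova_3x2(table: CohortTable) -> list[EffectResult]:
    """Aligned-rank-transform nonparametric factorial analysis.

    For each effect the responses are aligned (residual from the cell
    means plus that effect's own estimated contribution), ranked with
    midranks, and passed through the parametric repeated-measures ANOVA;
    only that effect's line is kept.
    """
    Y = table.wide()
    n, a, b = Y.shape
    gm = Y.mean()
    A = Y.mean(axis=(0, 2))
    B = Y.mean(axis=(0, 1))
    M = Y.mean(axis=0)
    resid = Y - M[None, :, :]
    estimates = {
        "model": np.broadcast_to((A - gm)[None, :, None], Y.shape),
        "condition": np.broadcast_to((B - gm)[None, None, :], Y.shape),
        "interaction": np.broadcast_to(
            (M - A[:, None] - B[None, :] + gm)[None, :, :], Y.shape
        ),
    }
    out = []
    for k, effect in enumerate(("model", "condition", "interaction")):
        aligned = resid + estimates[effect]
        ranked = stats.rankdata(aligned.ravel()).reshape(Y.shape)
        out.append(_anova_from_wide(ranked)[k])
    return out


def aligned_responses(table: CohortTable) -> dict[str, np.ndarray]:
    """The aligned (pre-rank) responses per effect, mainly for diagnostics."""
    Y = table.wide()
    gm = Y.mean()
    A = Y.mean(axis=(0, 2))
    B = Y.mean(axis=(0, 1))
    M = Y.mean(axis=0)
    resid = Y - M[None, :, :]
    return {
        "model": resid + np.broadcast_to((A - gm)[None, :, None], Y.shape),
        "condition": resid + np.broadcast_to((B - gm)[None, None, :], Y.shape),
        "interaction": resid
        + np.broadcast_to((M - A[:, None] - B[None, :] + gm)[None, :, :], Y.shape),
    }


def _paired_p(x: np.ndarray, y: np.ndarray) -> float:
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        return 1.0 if np.allclose(d.mean(), 0.0) else 0.0
    return float(stats.ttest_rel(x, y).pvalue)


def bonferroni_posthoc(
    table: CohortTable, family: PosthocFamily | str
) -> list[PosthocResult]:
    """Bonferroni-adjusted paired t-tests for one comparison family.

    Model families comprise 3 pairwise comparisons (adjusted alpha
    0.05 / 3 ~ 0.017); condition families 1 comparison per model (alpha
    0.05).  Adjusted p-values are the raw p times the family size, capped
    at 1.
    """
    family = PosthocFamily(family)
    Y = table.wide()
    out: list[PosthocResult] = []

    def add(label: str, x: np.ndarray, y: np.ndarray, m: int) -> None:
        p = min(1.0, _paired_p(x, y) * m)
        alpha_adj = ALPHA / m
        out.append(
            PosthocResult(
                comparison=label,
                mean_diff=float(np.mean(x - y)),
                p_adjusted=p,
                significant=p < ALPHA,
                alpha_adjusted=alpha_adj,
            )
        )

    models = [m.value for m in MODEL_ORDER]
    conds = [c.value for c in CONDITION_ORDER]
    if family is PosthocFamily.MODELS_WITHIN_CONDITION:
        for j, cond in enumerate(conds):
            for (i1, m1), (i2, m2) in combinations(enumerate(models), 2):
                add(f"{m1}_{cond} vs {m2}_{cond}", Y[:, i1, j], Y[:, i2, j], 3)
    elif family is PosthocFamily.CONDITIONS_WITHIN_MODEL:
        for i, model in enumerate(models):
            add(f"{model}_{conds[0]} vs {model}_{conds[1]}", Y[:, i, 0], Y[:, i, 1], 1)
    elif family is PosthocFamily.MODELS_POOLED:
        P = Y.mean(axis=2)
        for (i1, m1), (i2, m2) in combinations(enumerate(models), 2):
            add(f"{m1} vs {m2}", P[:, i1], P[:, i2], 3)
    else:  # CONDITIONS_POOLED
        P = Y.mean(axis=1)
        add(f"{conds[0]} vs {conds[1]}", P[:, 0], P[:, 1], 1)
    return out


@dataclass
class ParameterBlock:
    parameter: str
    used_art: bool
    normality_p: dict[tuple[str, str], float]
    effects: list[EffectResult]
    posthocs: dict[str, list[PosthocResult]] = field(default_factory=dict)


@dataclass
class FactorialReport:
    """Per-parameter factorial results in the layout of the summary table:
    interaction line first, then either simple-effect post-hocs (interaction
    significant) or main effects with their own post-hocs."""

    blocks: list[ParameterBlock]

    def to_dict(self) -> dict:
        def eff(e: EffectResult) -> dict:
            return {
                "effect": e.effect, "F": e.F, "df": list(e.df), "p": e.p,
                "eta2": e.eta2, "undefined": e.undefined,
                "significant": e.significant,
            }

        def ph(p: PosthocResult) -> dict:
            return {
                "comparison": p.comparison, "mean_diff": p.mean_diff,
                "p_adjusted": p.p_adjusted, "significant": p.significant,
                "alpha_adjusted": p.alpha_adjusted,
            }

        return {
            b.parameter: {
                "used_art": b.used_art,
                "normality_p": {f"{m}_{c}": v for (m, c), v in b.normality_p.items()},
                "effects": [eff(e) for e in b.effects],
                "posthocs": {k: [ph(p) for p in v] for k, v in b.posthocs.items()},
            }
            for b in self.blocks
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def render_text(self) -> str:
        lines = []
        for b in self.blocks:
            lines.append(f"== {b.parameter} ({'ART' if b.used_art else 'RM-ANOVA'}) ==")
            for e in b.effects:
                if e.undefined:
                    lines.append(f"  {e.effect}: F undefined (zero error SS)")
                else:
                    lines.append(
                        f"  {e.effect}: F({e.df[0]},{e.df[1]}) = {e.F:.3f}, "
                        f"p = {e.p:.4f}, eta2 = {e.eta2:.3f}"
                        + (" *" if e.significant else "")
                    )
            for famname, phs in b.posthocs.items():
                lines.append(f"  post-hoc [{famname}]:")
                for p in phs:
                    lines.append(
                        f"    {p.comparison}: diff = {p.mean_diff:+.2f}, "
                        f"p_adj = {p.p_adjusted:.4f}"
                        + (" *" if p.significant else "")
                    )
        return "\n".join(lines)

    def block(self, parameter: str) -> ParameterBlock:
        for b in self.blocks:
            if b.parameter == parameter:
                return b
        raise KeyError(parameter)


def run_factorial_pipeline(
    tables: Mapping[str, CohortTable],
    *,
    force_parametric: bool = False,
    classical_eta2: bool = False,
) -> FactorialReport:
    """Normality-routed factorial analysis of every parameter table.

    Per parameter: Shapiro-Wilk on the six cells routes to the parametric
    repeated-measures ANOVA (all cells normal at alpha = 0.05) or to ART;
    a significant interaction triggers simple-effect post-hocs (model pairs
    within each condition, condition pair within each model), otherwise
    significant main effects get their pooled post-hoc families.
    """
    blocks = []
    for name, table in tables.items():
        normality = shapiro_normality(table)
        use_art = (not force_parametric) and any(p < ALPHA for p in normality.values())
        effects = art_anova_3x2(table) if use_art else rm_anova_3x2(
            table, classical_eta2=classical_eta2
        )
        by_name = {e.effect: e for e in effects}
        posthocs: dict[str, list[PosthocResult]] = {}
        if by_name["interaction"].significant:
            posthocs[PosthocFamily.MODELS_WITHIN_CONDITION.value] = bonferroni_posthoc(
                table, PosthocFamily.MODELS_WITHIN_CONDITION
            )
            posthocs[PosthocFamily.CONDITIONS_WITHIN_MODEL.value] = bonferroni_posthoc(
                table, PosthocFamily.CONDITIONS_WITHIN_MODEL
            )
        else:
            if by_name["model"].significant:
                posthocs[PosthocFamily.MODELS_POOLED.value] = bonferroni_posthoc(
                    table, PosthocFamily.MODELS_POOLED
                )
            if by_name["condition"].significant:
                posthocs[PosthocFamily.CONDITIONS_POOLED.value] = bonferroni_posthoc(
                    table, PosthocFamily.CONDITIONS_POOLED
                )
        blocks.append(
            ParameterBlock(
                parameter=name,
                used_art=use_art,
                normality_p=normality,
                effects=effects,
                posthocs=posthocs,
            )
        )
    return FactorialReport(blocks=blocks)
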