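"""Synthetic-data generators with known ground truth for every analysis
stage: the insertion-line survival screen, the half-diallel cross, and the
multi-trait pleiotropy table.

All randomness flows from a single integer seed through a documented
``numpy.random.SeedSequence`` splitting scheme (one child stream per model
stratum), so a given seed reproduces a dataset byte-for-byte and the
per-stratum draws are stable under changes elsewhere.

The screen generator emulates the study conditions: lines measured in
replicate vials of same-sex flies, deaths recorded on a two-day census grid
(the recorded age is the census day on or after true death), a co-isogenic
control line raised in the same blocks with more replicate vials, and
normally distributed line, line-by-sex, vial, and individual effects.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import SEXES, validate_survival
from .diallel import DiallelData

_SEX_SIGN = {"male": -0.5, "female": 0.5}


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def snap_to_grid(ages: np.ndarray, interval: float, first: float | None = None) -> np.ndarray:
    """Census-grid recording: the grid day on or after the raw death time.

    Ages below the first census day are recorded at the first census (all
    flies alive at day 0; no non-positive life spans).
    """
    if first is None:
        first = interval
    steps = np.ceil((np.asarray(ages, dtype=float) - first) / interval - 1e-12)
    return first + interval * np.maximum(steps, 0)


@dataclasses.dataclass
class ScreenSimParams:
    """Generative parameters of the survival screen.

    Variances are in days^2: ``sigma2_line`` (among-line), ``sigma2_line_sex``
    (line-by-sex), ``sigma2_vial`` (among replicate vials within line and
    sex), ``sigma2_error`` (among individual flies within a vial). The
    vial-mean error variance seen by the screen ANOVA is
    ``sigma2_vial + sigma2_error / flies_per_vial``. Defaults reproduce the
    magnitudes of the original 1,332-line screen: line 31.39, line-by-sex
    25.24, and a vial-mean error of 45.02 (decomposed 25 + 100/5), with two
    vials of five same-sex flies per line and ten control vials per sex.
    """

    mu: float = 55.0
    sigma2_line: float = 31.39
    sigma2_line_sex: float = 25.24
    sigma2_vial: float = 25.0
    sigma2_error: float = 100.0
    n_lines: int = 1332
    vials_per_sex: int = 2
    flies_per_vial: int = 5
    sex_effect: float = 2.0
    census_interval: float = 2.0
    control_vials_per_sex: int = 10
    control_line: str = "control"
    block: str = "block1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_line", "sigma2_line_sex", "sigma2_vial", "sigma2_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_lines", "vials_per_sex", "flies_per_vial", "control_vials_per_sex"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")


def simulate_screen(params: ScreenSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the survival screen; returns (records, truth).

    Each fly's raw life span is
    mu + sex_effect/2 * (+1 female, -1 male) + line + line-by-sex + vial +
    individual draws, then snapped up to the census grid. The control line
    carries zero line and interaction effects. ``truth`` is a sidecar table
    of the drawn per-line effects (never embedded in the data file).
    """
    p = params
    rng_line, rng_ls, rng_vial, rng_ind = _rng_children(p.seed, 4)
    lines = [p.control_line] + [f"L{i:04d}" for i in range(1, p.n_lines + 1)]
    line_eff = np.concatenate([[0.0], rng_line.normal(0, np.sqrt(p.sigma2_line), p.n_lines)])
    ls_eff = {
        sex: np.concatenate(
            [[0.0], rng_ls.normal(0, np.sqrt(p.sigma2_line_sex), p.n_lines)]
        )
        for sex in SEXES
    }
    rows: list[pd.DataFrame] = []
    for i, name in enumerate(lines):
        n_vials = p.control_vials_per_sex if name == p.control_line else p.vials_per_sex
        for sex in SEXES:
            base = (
                p.mu
                + p.sex_effect * _SEX_SIGN[sex]
                + line_eff[i]
                + ls_eff[sex][i]
            )
            vial_draw = rng_vial.normal(0, np.sqrt(p.sigma2_vial), n_vials)
            ind = rng_ind.normal(
                0, np.sqrt(p.sigma2_error), (n_vials, p.flies_per_vial)
            )
            raw = base + vial_draw[:, None] + ind
            ages = snap_to_grid(raw.ravel(), p.census_interval)
            rows.append(
                pd.DataFrame(
                    {
                        "block": p.block,
                        "line": name,
                        "sex": sex,
                        "vial": np.repeat(
                            [f"v{j + 1}" for j in range(n_vials)], p.flies_per_vial
                        ),
                        "death_age": ages,
                    }
                )
            )
    records = pd.concat(rows, ignore_index=True)
    records = validate_survival(records, census_interval=p.census_interval)
    truth = pd.DataFrame(
        {
            "line": lines,
            "line_effect": line_eff,
            "line_sex_male": ls_eff["male"],
            "line_sex_female": ls_eff["female"],
        }
    )
    return records, truth


@dataclasses.dataclass
class DiallelSimParams:
    """Generative parameters of the half-diallel cross.

    ``gca`` (length ``n_parents``, sums to zero) and ``sca`` (symmetric,
    zero diagonal) define the cross-mean structure
    E[X_ij] = mu + g_i + g_j + s_ij; ``sex_gca``/``sex_sca`` add analogous
    sex-interaction structure with opposite signs in the two sexes. Only the
    doubly-centred part of ``sca`` is estimable by a combining-ability
    analysis. Defaults match the study design: ten parents, eight replicate
    vials per cross per sex.
    """

    n_parents: int = 10
    mu: float = 55.0
    gca: np.ndarray | None = None
    sca: np.ndarray | None = None
    sex_gca: np.ndarray | None = None
    sex_sca: np.ndarray | None = None
    sex_effect: float = 2.0
    sigma2_vial: float = 4.0
    sigma2_error: float = 9.0
    reps_per_cross_per_sex: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_parents
        if n < 3:
            raise ValueError("a half-diallel needs at least 3 parents")
        if self.sigma2_vial < 0 or self.sigma2_error < 0:
            raise ValueError("variances must be non-negative")
        if self.reps_per_cross_per_sex < 1:
            raise ValueError("need at least one replicate vial per cross per sex")
        if self.gca is None:
            self.gca = np.zeros(n)
        self.gca = np.asarray(self.gca, dtype=float)
        if self.gca.shape != (n,):
            raise ValueError("gca must have length n_parents")
        if abs(self.gca.sum()) > 1e-8 * max(1.0, np.abs(self.gca).max()):
            raise ValueError("gca effects must sum to zero")
        for name in ("sca", "sex_sca"):
            m = getattr(self, name)
            if m is None:
                setattr(self, name, np.zeros((n, n)))
                continue
            m = np.asarray(m, dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be an n_parents x n_parents matrix")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if not np.allclose(np.diag(m), 0, atol=1e-10):
                raise ValueError(f"{name} must have a zero diagonal")
            setattr(self, name, m)
        if self.sex_gca is None:
            self.sex_gca = np.zeros(n)
        self.sex_gca = np.asarray(self.sex_gca, dtype=float)
        if self.sex_gca.shape != (n,):
            raise ValueError("sex_gca must have length n_parents")


def simulate_diallel(params: DiallelSimParams) -> tuple[DiallelData, dict]:
    """Simulate replicate vial means for every cross of a half-diallel.

    Only i<j cells are generated (no selfs, no reciprocals). Each vial value
    is the cell expectation plus among-vial and residual noise. Returns the
    data and a ground-truth dict with the parameter arrays.
    """
    p = params
    n = p.n_parents
    (rng,) = _rng_children(p.seed, 1)
    parents = [f"P{i + 1:02d}" for i in range(n)]
    sd = float(np.sqrt(p.sigma2_vial + p.sigma2_error))
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            for sex in SEXES:
                s = 2 * _SEX_SIGN[sex]  # -1 male, +1 female
                mean = (
                    p.mu
                    + p.sex_effect * _SEX_SIGN[sex]
                    + (p.gca[i] + s * p.sex_gca[i])
                    + (p.gca[j] + s * p.sex_gca[j])
                    + (p.sca[i, j] + s * p.sex_sca[i, j])
                )
                vals = mean + rng.normal(0, sd, p.reps_per_cross_per_sex)
                for k, v in enumerate(vals):
                    rows.append(
                        {
                            "parent_i": parents[i],
                            "parent_j": parents[j],
                            "sex": sex,
                            "vial": f"v{k + 1}",
                            "value": v,
                        }
                    )
    data = DiallelData(pd.DataFrame(rows))
    truth = {
        "parents": parents,
        "mu": p.mu,
        "gca": p.gca.copy(),
        "sca": p.sca.copy(),
        "sex_gca": p.sex_gca.copy(),
        "sex_sca": p.sex_sca.copy(),
    }
    return data, truth


DEFAULT_TRAITS = ("life span", "starvation resistance", "chill coma recovery", "climbing")


@dataclasses.dataclass
class PleiotropySimParams:
    """Generative parameters for multi-trait line-mean deviations.

    ``covariance`` is a symmetric positive-semidefinite matrix over the
    trait x sex x age cells listed in ``cells`` (order defines the matrix
    axes). ``lines_measured`` optionally restricts a trait to the first k
    lines (unmeasured cells are missing), emulating traits scored on a
    subset of lines.
    """

    n_lines: int = 50
    trait_names: Sequence[str] = DEFAULT_TRAITS
    sexes: Sequence[str] = SEXES
    ages: Sequence[int] = (1, 6)
    covariance: np.ndarray | None = None
    lines_measured: Mapping[str, int] | None = None
    seed: int = 0

    @property
    def cells(self) -> list[tuple[str, str, int]]:
        return [
            (t, s, a) for t in self.trait_names for s in self.sexes for a in self.ages
        ]

    def __post_init__(self) -> None:
        k = len(self.cells)
        if self.covariance is None:
            self.covariance = default_pleiotropy_covariance(
                self.trait_names, self.sexes, self.ages
            )
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (k, k):
            raise ValueError(
                f"covariance must be {k}x{k} to match the trait x sex x age cells"
            )
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        w = np.linalg.eigvalsh(self.covariance)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError(
                f"covariance is not positive semidefinite (eigenvalue {w.min():.3g} < 0)"
            )


def default_pleiotropy_covariance(
    traits: Sequence[str] = DEFAULT_TRAITS,
    sexes: Sequence[str] = SEXES,
    ages: Sequence[int] = (1, 6),
) -> np.ndarray:
    """Default covariance of standardised line-mean deviations.

    A separable structure: a cross-trait correlation matrix (moderate
    positive life-span/stress correlations, a negative starvation/climbing
    correlation, magnitudes ~0.3 as observed for these traits) Kronecker a
    same-trait cross-sex correlation of 0.7 and cross-age correlation of
    0.5. Separable products of PSD factors are PSD by construction.
    """
    base = {
        ("life span", "starvation resistance"): 0.30,
        ("life span", "chill coma recovery"): 0.33,
        ("life span", "climbing"): 0.15,
        ("starvation resistance", "chill coma recovery"): 0.20,
        ("starvation resistance", "climbing"): -0.33,
        ("chill coma recovery", "climbing"): -0.15,
    }
    t = len(traits)
    R = np.eye(t)
    for a in range(t):
        for b in range(a + 1, t):
            r = base.get((traits[a], traits[b]), base.get((traits[b], traits[a]), 0.1))
            R[a, b] = R[b, a] = r
    S = np.eye(len(sexes)) * (1 - 0.7) + 0.7
    A = np.eye(len(ages)) * (1 - 0.5) + 0.5
    return np.kron(R, np.kron(S, A))


def simulate_pleiotropy(params: PleiotropySimParams) -> pd.DataFrame:
    """Multivariate-normal line-mean deviations over trait x sex x age cells.

    Returns a long table (line, sex, age_weeks, trait, value); values are
    deviations from the control, so the population mean is zero. Cells of a
    trait beyond its ``lines_measured`` count are omitted.
    """
    p = params
    (rng,) = _rng_children(p.seed, 1)
    draws = rng.multivariate_normal(
        np.zeros(len(p.cells)), p.covariance, size=p.n_lines, method="eigh"
    )
    lines = [f"L{i + 1:04d}" for i in range(p.n_lines)]
    rows = []
    for idx, (trait, sex, age) in enumerate(p.cells):
        measured = p.n_lines
        if p.lines_measured and trait in p.lines_measured:
            measured = int(p.lines_measured[trait])
        for li in range(measured):
            rows.append(
                {
                    "line": lines[li],
                    "sex": sex,
                    "age_weeks": age,
                    "trait": trait,
                    "value": draws[li, idx],
                }
            )
    return pd.DataFrame(rows)
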