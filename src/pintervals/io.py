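"""File readers/writers and batch interval reports.

All on-disk formats are tab-separated text with a header line; ``#`` lines
are comments.  Two prior-table dialects exist:

``delta<TAB>prob``
    a discrete prior on the standardized effect size, probabilities
    renormalized on read (with a warning if they are off by more than 1e-6);
``or<TAB>count``
    a tabulated odds-ratio distribution (locus counts), with the total
    number of tests on a ``# M=<int>`` comment line.

Study tables follow the layout label/cases/controls/one-sided P-value; the
effective sample size of a row is half the harmonic mean of the group
sizes and scales the prior variance of the standardized effect onto the
statistic scale, row by row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .conjugate import (
    ConjugateNormalPrior,
    classical_p_interval,
    conjugate_prediction_interval,
)
from .effect_size import EffectSizeTable
from .mixture import (
    TabulatedEffectPrior,
    discretize_prior,
    mixture_prediction_interval,
    tabulated_prior_from_or_table,
)
from .transforms import Sidedness, p_to_stat

__all__ = [
    "StudyRow",
    "IntervalReportRow",
    "read_study_table",
    "read_prior_table",
    "write_interval_report",
    "batch_intervals",
    "generate_fixtures",
]

logger = logging.getLogger("pintervals")

_STUDY_COLUMNS = ("label", "cases", "controls", "p_one_sided")


@dataclass(frozen=True)
class StudyRow:
    """One study: group sizes and the observed one-sided P-value."""

    label: str
    cases: int
    controls: int
    p_one_sided: float

    def __post_init__(self) -> None:
        if self.cases <= 0 or self.controls <= 0:
            raise ValueError(f"{self.label}: group sizes must be positive")
        if not 0.0 < self.p_one_sided < 1.0:
            raise ValueError(
                f"{self.label}: P-value must lie in (0, 1), "
                f"got {self.p_one_sided}"
            )

    @property
    def effective_n(self) -> float:
        return 1.0 / (1.0 / self.cases + 1.0 / self.controls)


@dataclass(frozen=True)
class IntervalReportRow:
    """One study-by-method line of a batch interval report."""

    label: str
    method: str
    level: float
    p_lower: float
    p_upper: float

    @property
    def neglog10_lower(self) -> float:
        """-log10 of p_upper: the lower bound on the -log10 scale."""
        return -math.log10(self.p_upper)

    @property
    def neglog10_upper(self) -> float:
        return -math.log10(self.p_lower)


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    return df.rename(columns=lambda c: c.strip().lower())


def read_study_table(path) -> list[StudyRow]:
    """Read and validate a study table; malformed rows name their line."""
    df = _read_table(path)
    if df.empty and df.columns.size == 0:
        logger.warning("study table %s is empty", path)
        return []
    missing = set(_STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows: list[StudyRow] = []
    for i, rec in df.iterrows():
        try:
            rows.append(
                StudyRow(
                    label=str(rec["label"]),
                    cases=int(rec["cases"]),
                    controls=int(rec["controls"]),
                    p_one_sided=float(rec["p_one_sided"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, data row {i + 1}: {exc}") from exc
    return rows


def read_prior_table(path) -> TabulatedEffectPrior | EffectSizeTable:
    """Read a prior table, dispatching on its header dialect."""
    path = Path(path)
    df = _read_table(path)
    cols = set(df.columns)
    if {"delta", "prob"} <= cols:
        values = df["delta"].astype(float).to_numpy()
        probs = df["prob"].astype(float).to_numpy()
        order = np.argsort(values)
        values, probs = values[order], probs[order]
        total = probs.sum()
        if abs(total - 1.0) > 1e-6:
            logger.warning(
                "prior table %s probabilities sum to %.8f; renormalizing",
                path,
                total,
            )
        return TabulatedEffectPrior(values, probs / total, scale="delta")
    if {"or", "count"} <= cols:
        m = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#") and "M=" in line.replace(" ", ""):
                    m = int(line.replace(" ", "").split("M=")[1])
        if m is None:
            raise ValueError(f"{path}: or/count dialect requires a '# M=' line")
        rows = tuple(
            (float(o), int(c))
            for o, c in zip(df["or"].astype(float), df["count"].astype(int))
        )
        return EffectSizeTable(rows=rows, total_tests=m)
    raise ValueError(
        f"{path}: expected columns delta/prob or or/count, got {sorted(cols)}"
    )


def write_interval_report(rows: list[IntervalReportRow], out) -> None:
    """Write a batch report: 3-significant-figure display columns plus
    machine-precision columns, so tables and regression checks coexist."""
    df = pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "method": [r.method for r in rows],
            "level": [r.level for r in rows],
            "p_lower": [f"{r.p_lower:.3g}" for r in rows],
            "p_upper": [f"{r.p_upper:.3g}" for r in rows],
            "neglog10_lower": [f"{r.neglog10_lower:.4f}" for r in rows],
            "neglog10_upper": [f"{r.neglog10_upper:.4f}" for r in rows],
            "p_lower_exact": [repr(r.p_lower) for r in rows],
            "p_upper_exact": [repr(r.p_upper) for r in rows],
        }
    )
    df.to_csv(out, sep="\t", index=False)


def batch_intervals(
    rows: list[StudyRow],
    s0_sq: float | None = None,
    prior_table: EffectSizeTable | TabulatedEffectPrior | None = None,
    methods: tuple[str, ...] = ("p_interval", "conjugate", "mixture"),
    level: float = 0.95,
) -> list[IntervalReportRow]:
    """Prediction intervals for every (study row, method) combination.

    The conjugate and discretized-mixture methods scale the standardized
    prior variance per row, sigma0^2 = N * s0_sq; a tabulated odds-ratio
    prior is used as-is by the mixture method.  The classical P-interval
    ignores the prior entirely.
    """
    if any(m in ("conjugate", "mixture") for m in methods) and (
        s0_sq is None and prior_table is None
    ):
        raise ValueError("Bayesian methods need s0_sq or a prior table")
    out: list[IntervalReportRow] = []
    for row in rows:
        z = p_to_stat(row.p_one_sided, conv=Sidedness.ONE_SIDED_UPPER)
        n = row.effective_n
        for method in methods:
            if method == "p_interval":
                iv = classical_p_interval(row.p_one_sided, level)
            elif method == "conjugate":
                if s0_sq is None:
                    raise ValueError("conjugate method requires s0_sq")
                prior = ConjugateNormalPrior(s0_sq=s0_sq, effective_n=n)
                iv = conjugate_prediction_interval(z, prior, level)
            elif method == "mixture":
                if isinstance(prior_table, EffectSizeTable):
                    prior = tabulated_prior_from_or_table(prior_table, n)
                elif isinstance(prior_table, TabulatedEffectPrior):
                    prior = prior_table
                else:
                    prior = discretize_prior(0.0, s0_sq, effective_n=n)
                from .transforms import TestSpec

                spec = TestSpec(effective_n=n)
                iv = mixture_prediction_interval(
                    t_obt=z, prior=prior, spec=spec, level=level
                )
            else:
                raise ValueError(f"unknown method {method!r}")
            out.append(
                IntervalReportRow(
                    label=row.label,
                    method=method,
                    level=level,
                    p_lower=iv.p_lower,
                    p_upper=iv.p_upper,
                )
            )
    return out


# ---------------------------------------------------------------------------
# fixtures


def generate_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Write small synthetic inputs exercising every file format.

    Produces an L-shaped synthetic odds-ratio prior table (heavy mass near
    OR = 1.005 with a thin tail to OR ~ 1.5, the qualitative shape of
    empirical genome-wide effect-size distributions), a synthetic study
    table, and coverage-scenario configs.  Byte-identical across runs at a
    fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    paths: dict[str, Path] = {}

    # synthetic L-shaped OR table: counts fall off geometrically with OR
    m_total = 300_000
    or_grid = [1.1, 1.15, 1.2, 1.3, 1.4, 1.5]
    base = np.array([60.0, 30.0, 15.0, 6.0, 2.0, 1.0])
    counts = np.maximum(rng.poisson(base), 1)
    prior_path = outdir / "prior_or_synthetic.tsv"
    lines = [
        "# synthetic L-shaped effect-size table (not an empirical dataset)",
        f"# M={m_total}",
        "or\tcount",
    ]
    lines += [f"{o}\t{c}" for o, c in zip(or_grid, counts)]
    prior_path.write_text("\n".join(lines) + "\n")
    paths["prior_table"] = prior_path

    # synthetic study table: group sizes and one-sided P-values
    study_path = outdir / "studies_synthetic.tsv"
    labels = ["study_a", "study_b", "study_c", "study_d"]
    cases = rng.integers(2000, 10_000, size=4)
    controls = rng.integers(2000, 10_000, size=4)
    pvals = np.round(10.0 ** rng.uniform(-6, -0.5, size=4), 10)
    lines = ["# synthetic study table", "label\tcases\tcontrols\tp_one_sided"]
    lines += [
        f"{lb}\t{ca}\t{co}\t{pv:.6g}"
        for lb, ca, co, pv in zip(labels, cases, controls, pvals)
    ]
    study_path.write_text("\n".join(lines) + "\n")
    paths["study_table"] = study_path

    # coverage-scenario configs
    scenarios = {
        "coverage_none.yaml": dict(
            generating_sigma0_sq=0.25,
            method="p_interval",
            level=0.8,
            reps=20_000,
            seed=int(seed),
        ),
        "coverage_threshold.yaml": dict(
            generating_sigma0_sq=0.25,
            method="p_interval",
            level=0.8,
            selection=dict(mode="threshold", p_high=0.001),
            reps=20_000,
            seed=int(seed),
        ),
        "coverage_window.yaml": dict(
            generating_sigma0_sq=0.25,
            method="p_interval",
            level=0.8,
            selection=dict(mode="window", p_low=0.045, p_high=0.055),
            reps=20_000,
            seed=int(seed),
        ),
        "coverage_min_of_L.yaml": dict(
            generating_sigma0_sq=0.25,
            method="p_interval",
            level=0.8,
            selection=dict(mode="min_of_L", L=10_000),
            reps=2_000,
            seed=int(seed),
        ),
    }
    import yaml as _yaml

    for name, cfg in scenarios.items():
        p = outdir / name
        p.write_text(_yaml.safe_dump(cfg, sort_keys=True))
        paths[name] = p
    return paths
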