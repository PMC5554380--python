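"""Synthetic cohorts and Ct matrices with the statistical structure the
analysis pipeline assumes.

Two generators are provided:

``simulate_profiling``
    A two-panel TaqMan-array discovery experiment: 377 miRNAs per panel over a
    small 4/5/4/3 (ASD/TS/TS+ASD/NC) sample set.  Each well's Ct is a
    per-miRNA baseline plus a per-sample loading offset (shared across the
    array, emulating loaded cDNA mass), a group effect on designated marker
    miRNAs, and Gaussian noise; wells drop out (are flagged) at a configurable
    probability.  Designated stable-control miRNAs have near-zero biological
    variance and high abundance, so the control-ranking stage should find
    them.

``simulate_validation_cohort``
    A 30/24/25/25 single-assay validation cohort: the marker miRNA's ΔCt is
    Normal(μ_g, σ) per group, with the positive class (ASD) at the lowest ΔCt
    (upregulated).  YGTSS tic-severity scores follow a latent linear model on
    the marker ΔCt; IQ and ADOS item scores are group-conditional Gaussians
    (controls have ADOS fixed at 0).

Both are bit-reproducible for a fixed seed + config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ADOS_COLUMNS, GROUPS, CohortTable, CtMatrix
from .normalize import DeltaCtMatrix

#: Marker miRNA name used by default throughout the synthetic pipeline.
MARKER = "miR-140-3p"

#: Group-conditional (mean, SD) for IQ, matching a realistic clinical cohort
#: where the ASD group scores lower.
IQ_PARAMS: dict[str, tuple[float, float]] = {
    "ASD": (59.4, 20.6),
    "TS": (93.7, 19.1),
    "TS+ASD": (94.6, 8.9),
    "NC": (80.9, 24.5),
}

#: Group-conditional (mean, SD) per ADOS item A–D.  Zeros are exact: controls
#: score 0 on every item, TS patients 0 on items A–C.
ADOS_PARAMS: dict[str, tuple[tuple[float, float], ...]] = {
    "ASD": ((7.3, 2.3), (7.6, 2.1), (3.0, 2.5), (3.5, 1.6)),
    "TS": ((0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (2.4, 1.6)),
    "TS+ASD": ((6.4, 3.2), (8.5, 3.9), (3.1, 4.3), (3.7, 1.9)),
    "NC": ((0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0)),
}


@dataclass
class SimulationConfig:
    """All tunable knobs of the synthetic-data generators.

    Defaults encode the study conditions the pipeline is meant to analyse:
    profiling group sizes 4/5/4/3 and validation group sizes 30/24/25/25;
    per-group marker ΔCt means chosen so the pairwise separations reproduce
    the binormal AUCs of the reference analysis (ASD vs NC ≈ 0.71, vs TS ≈
    0.73, vs TS+ASD ≈ 0.78 at σ = 1); and a YGTSS latent line
    y = 4.537·ΔCt − 3.269 whose noise SD yields a Spearman correlation ≈ 0.33
    at n = 104.
    """

    seed: int = 0
    # --- profiling arm -----------------------------------------------------
    profiling_group_sizes: dict[str, int] = field(
        default_factory=lambda: {"ASD": 4, "TS": 5, "TS+ASD": 4, "NC": 3}
    )
    n_mirnas_per_panel: int = 377
    panels: tuple[str, ...] = ("A", "B")
    baseline_ct_range: tuple[float, float] = (22.0, 35.0)
    baseline_sd_range: tuple[float, float] = (0.5, 1.5)
    loading_sd: float = 0.5
    n_stable_controls: int = 3
    control_ct_range: tuple[float, float] = (19.0, 23.0)
    control_sd: float = 0.02
    #: Ct shift (cycles) applied to marker rows per group; negative = more
    #: template = upregulation.  One marker per panel by default.
    marker_shifts: dict[str, float] = field(default_factory=lambda: {"ASD": -3.0})
    n_markers_per_panel: int = 1
    flag_prob: float = 0.05
    flag_mode: str = "uniform"  # or "high_ct": dropout concentrates at high Ct
    flag_high_ct_midpoint: float = 33.0
    flag_high_ct_scale: float = 1.5
    # --- validation arm ----------------------------------------------------
    validation_group_sizes: dict[str, int] = field(
        default_factory=lambda: {"ASD": 30, "TS": 24, "TS+ASD": 25, "NC": 25}
    )
    marker_group_means: dict[str, float] = field(
        default_factory=lambda: {"ASD": 2.0, "TS": 2.867, "TS+ASD": 3.092, "NC": 2.783}
    )
    marker_sd: float = 1.0
    #: Non-marker validated miRNAs carried along as null rows.
    null_validation_mirnas: tuple[str, ...] = ("miR-30d", "miR-148a*", "miR-222")
    null_validation_mean: float = 3.0
    null_validation_sd: float = 1.0
    # --- clinical-score model ----------------------------------------------
    ygtss_slope: float = 4.537
    ygtss_intercept: float = -3.269
    ygtss_sd: float = 14.0
    round_scores: bool = True

    def validate(self) -> None:
        for name, sizes in (
            ("profiling_group_sizes", self.profiling_group_sizes),
            ("validation_group_sizes", self.validation_group_sizes),
        ):
            bad = set(sizes) - set(GROUPS)
            if bad:
                raise ValueError(f"{name}: unknown groups {sorted(bad)}")
            if any(n < 2 for n in sizes.values()):
                raise ValueError(f"{name}: every group entering a two-class test needs n ≥ 2")
        if not 0.0 <= self.flag_prob <= 1.0:
            raise ValueError("flag_prob must be in [0, 1]")
        for sd in (
            self.loading_sd,
            self.control_sd,
            self.marker_sd,
            self.null_validation_sd,
            self.ygtss_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be ≥ 0")
        if self.flag_mode not in ("uniform", "high_ct"):
            raise ValueError(f"unknown flag_mode {self.flag_mode!r}")
        if self.n_mirnas_per_panel < self.n_stable_controls + self.n_markers_per_panel:
            raise ValueError("panel too small for the requested controls and markers")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class ProfilingTruth:
    """Ground truth behind a simulated profiling experiment."""

    sample_groups: dict[str, str]
    loading_offsets: dict[str, float]
    de_mirnas: dict[str, list[str]]  # panel -> marker rows with a group effect
    stable_controls: dict[str, list[str]]  # panel -> designated controls
    n_flagged: dict[str, int]


@dataclass
class ValidationTruth:
    """Ground truth behind a simulated validation cohort."""

    marker_group_means: dict[str, float]
    marker_sd: float
    ygtss_slope: float
    ygtss_intercept: float
    ygtss_sd: float
    latent_ygtss: pd.Series


def _sample_ids(sizes: Mapping[str, int], prefix: str = "") -> list[tuple[str, str]]:
    out = []
    for group in GROUPS:
        for i in range(sizes.get(group, 0)):
            label = group.replace("+", "")
            out.append((f"{prefix}{label}{i + 1:02d}", group))
    return out


def simulate_profiling(
    config: SimulationConfig, seed: int | None = None
) -> tuple[dict[str, CtMatrix], ProfilingTruth]:
    """Generate per-panel Ct matrices plus their ground-truth record."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    ids = _sample_ids(config.profiling_group_sizes, prefix="P-")
    samples = [s for s, _ in ids]
    groups = {s: g for s, g in ids}
    loading = {s: float(rng.normal(0.0, config.loading_sd)) for s in samples}

    panels: dict[str, CtMatrix] = {}
    de: dict[str, list[str]] = {}
    stable: dict[str, list[str]] = {}
    n_flagged: dict[str, int] = {}
    for panel in config.panels:
        n = config.n_mirnas_per_panel
        names = [f"{panel}-miR-{i + 1:03d}" for i in range(n)]
        # designated stable controls: abundant and nearly variance-free
        ctrl_names = [f"{panel}-ctrl-{j + 1}" for j in range(config.n_stable_controls)]
        marker_names = [f"{panel}-marker-{j + 1}" for j in range(config.n_markers_per_panel)]
        names[: config.n_stable_controls] = ctrl_names
        names[
            config.n_stable_controls : config.n_stable_controls + config.n_markers_per_panel
        ] = marker_names

        baseline = rng.uniform(*config.baseline_ct_range, size=n)
        noise_sd = rng.uniform(*config.baseline_sd_range, size=n)
        baseline[: config.n_stable_controls] = rng.uniform(
            *config.control_ct_range, size=config.n_stable_controls
        )
        noise_sd[: config.n_stable_controls] = config.control_sd

        ct = np.empty((n, len(samples)))
        for j, s in enumerate(samples):
            shift = np.zeros(n)
            g = groups[s]
            if g in config.marker_shifts:
                for name in marker_names:
                    shift[names.index(name)] = config.marker_shifts[g]
            ct[:, j] = baseline + loading[s] + shift + rng.normal(0.0, noise_sd, size=n)

        if config.flag_prob == 0.0:
            flag = np.zeros_like(ct, dtype=bool)
        elif config.flag_mode == "uniform":
            flag = rng.random(ct.shape) < config.flag_prob
        else:  # high_ct: dropout probability rises with Ct (low abundance)
            logistic = 1.0 / (
                1.0 + np.exp(-(ct - config.flag_high_ct_midpoint) / config.flag_high_ct_scale)
            )
            # scaled so the average well keeps roughly the configured rate
            p = config.flag_prob * logistic / max(float(logistic.mean()), 1e-12)
            flag = rng.random(ct.shape) < np.clip(p, 0.0, 1.0)

        ct_df = pd.DataFrame(ct, index=names, columns=samples)
        flag_df = pd.DataFrame(flag, index=names, columns=samples)
        panels[panel] = CtMatrix(ct_df, flag_df, panel=panel)
        de[panel] = marker_names
        stable[panel] = ctrl_names
        n_flagged[panel] = int(flag.sum())

    truth = ProfilingTruth(
        sample_groups=groups,
        loading_offsets=loading,
        de_mirnas=de,
        stable_controls=stable,
        n_flagged=n_flagged,
    )
    return panels, truth


def _round_maybe(values: np.ndarray, config: SimulationConfig) -> np.ndarray:
    return np.rint(values) if config.round_scores else values


def simulate_validation_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[DeltaCtMatrix, CohortTable, ValidationTruth]:
    """Generate the validation-arm ΔCt table, cohort metadata, and truth.

    The marker row's ΔCt is Normal(μ_g, σ) per group.  YGTSS is generated from
    the configured latent line on the marker ΔCt plus Gaussian noise, then
    rounded (rounding last, so the latent model stays exact).  ADOS items are
    group-conditional, with structural zeros for groups without the trait; IQ
    is group-conditional Gaussian.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    ids = _sample_ids(config.validation_group_sizes, prefix="V-")
    samples = [s for s, _ in ids]
    group_of = {s: g for s, g in ids}

    mu = np.array([config.marker_group_means[group_of[s]] for s in samples])
    marker_dct = mu + rng.normal(0.0, config.marker_sd, size=len(samples))

    rows = {MARKER: marker_dct}
    for name in config.null_validation_mirnas:
        rows[name] = config.null_validation_mean + rng.normal(
            0.0, config.null_validation_sd, size=len(samples)
        )
    values = pd.DataFrame(rows, index=samples).T

    latent_ygtss = config.ygtss_slope * marker_dct + config.ygtss_intercept
    ygtss = latent_ygtss + rng.normal(0.0, config.ygtss_sd, size=len(samples))

    table = pd.DataFrame(index=pd.Index(samples, name="sample"))
    table["group"] = [group_of[s] for s in samples]
    iq = np.array(
        [rng.normal(*IQ_PARAMS[group_of[s]]) for s in samples]
    )
    table["IQ"] = np.clip(_round_maybe(iq, config), 1.0, None)
    table["YGTSS"] = _round_maybe(ygtss, config)
    for item_idx, col in enumerate(ADOS_COLUMNS):
        scores = np.empty(len(samples))
        for i, s in enumerate(samples):
            mean, sd = ADOS_PARAMS[group_of[s]][item_idx]
            scores[i] = 0.0 if sd == 0.0 and mean == 0.0 else rng.normal(mean, sd)
        table[col] = np.clip(_round_maybe(scores, config), 0.0, None)

    dct = DeltaCtMatrix(
        values=values,
        controls=("miR-146a",),
        reference=pd.Series(0.0, index=values.columns),
        provenance={"source": "simulate_validation_cohort", "seed": int(config.seed if seed is None else seed)},
    )
    cohort = CohortTable(table)
    truth = ValidationTruth(
        marker_group_means=dict(config.marker_group_means),
        marker_sd=config.marker_sd,
        ygtss_slope=config.ygtss_slope,
        ygtss_intercept=config.ygtss_intercept,
        ygtss_sd=config.ygtss_sd,
        latent_ygtss=pd.Series(latent_ygtss, index=samples),
    )
    return dct, cohort, truth
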