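"""End-to-end study pipeline and report rendering.

Chains the stages — optional synthetic generation, new-user cohort
construction, exposure computation per gap policy, covariate derivation and
the statistical layer — writing every artifact plus a run manifest (config
hash, seed, library versions, per-stage row counts) so a run is auditable
and reproducible: the same configuration and seed yield byte-identical
outputs.

Rendering follows claims-study reporting conventions: categorical cells as
``n (%)`` with percentages rounded half-up to one decimal, continuous cells
as ``mean (SD)`` (with range where customary), odds ratios as
``OR (lower-upper)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .claims import ClaimsBundle
from .cohort import build_cohort
from .covariates import CodeMap, DEFAULT_CODE_MAP, COMORBIDITY_NAMES, build_covariates
from .exposure import GapPolicy, compute_exposure
from .stats import check_multicollinearity, fit_linear, fit_or_table, incidence, km_estimate
from .synthetic import SimulationConfig, generate

__all__ = [
    "StudyConfig",
    "run_pipeline",
    "render_table1",
    "render_or_table",
    "format_count_pct",
    "load_code_map",
]

#: covariate columns entering the logistic models, in reporting order
MODEL_COVARIATES = (
    "calendar_year_2018",
    "sex_male",
    "age_years",
    "n_visits",
    "mean_visit_interval_days",
    "n_concomitant_classes",
    *COMORBIDITY_NAMES,
    "cci",
)


@dataclass
class StudyConfig:
    """Study-level parameters (windows, gap policies, adherence cut-off)."""

    gap_policy_days: list[int] = field(default_factory=lambda: [90, 30])
    pdc_threshold: float = 0.80
    pre_index_days: int = 180
    followup_days: int = 365
    codemap_path: str | None = None
    seed: int = 0
    output_dir: str = "results"

    def validate(self) -> "StudyConfig":
        if not 0 < self.pdc_threshold < 1:
            raise ValueError("pdc_threshold must lie in (0, 1)")
        if self.pre_index_days <= 0 or self.followup_days <= 0:
            raise ValueError("windows must be positive")
        if not self.gap_policy_days:
            raise ValueError("need at least one gap policy")
        return self

    @classmethod
    def from_yaml(cls, path: Path | str) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown study config keys: {sorted(unknown)}")
        return cls(**data).validate()


def load_code_map(path: Path | str | None) -> CodeMap:
    """Code map from YAML (``comorbidities`` / ``drug_classes`` sections)."""
    if path is None:
        return DEFAULT_CODE_MAP
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    if "comorbidities" in data:
        kwargs["comorbidities"] = {
            name: tuple(prefixes) for name, prefixes in data["comorbidities"].items()
        }
    if "drug_classes" in data:
        kwargs["drug_classes"] = dict(data["drug_classes"])
    return CodeMap(**kwargs)


# ---------------------------------------------------------------------------
# rendering


def _round1(value: float) -> str:
    return str(Decimal(repr(float(value))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_count_pct(count: int, total: int) -> str:
    """``"1029 (77.5)"`` — percent of total, one decimal, round half-up."""
    pct = 0.0 if total == 0 else 100.0 * count / total
    return f"{count} ({_round1(pct)})"


def _mean_sd(values, with_range: bool = False) -> str:
    values = np.asarray(values, dtype=float)
    s = f"{_round1(values.mean())} ({_round1(values.std(ddof=1))})"
    if with_range:
        s += f" ({_round1(values.min())}–{_round1(values.max())})"
    return s


def _or_ci(or_, lo, hi) -> str:
    if not np.isfinite(or_):
        return "-"
    return f"{or_:.3f} ({lo:.3f}–{hi:.3f})"


def render_table1(covariates: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics analogue: one formatted row per variable.

    Every count is taken directly from the covariate table — nothing is
    recomputed at render time.
    """
    n = len(covariates)
    rows: list[tuple[str, str]] = [
        ("n", str(n)),
        ("Calendar year 2018, n (%)", format_count_pct(int(covariates["calendar_year_2018"].sum()), n)),
        ("Calendar year 2019, n (%)", format_count_pct(int((~covariates["calendar_year_2018"]).sum()), n)),
        ("Sex, male, n (%)", format_count_pct(int(covariates["sex_male"].sum()), n)),
        ("Age at the index date, years, mean (SD) (range)", _mean_sd(covariates["age_years"], with_range=True)),
        ("Number of outpatient visits, mean (SD)", _mean_sd(covariates["n_visits"])),
        ("Mean interval between outpatient visits, days, mean (SD)", _mean_sd(covariates["mean_visit_interval_days"])),
    ]
    for col in covariates.columns:
        if col.startswith("rx_"):
            label = col[3:].replace("_", " ")
            rows.append((f"Concomitant {label}, n (%)", format_count_pct(int(covariates[col].sum()), n)))
    rows.append(("Number of concomitant drug classes, mean (SD)", _mean_sd(covariates["n_concomitant_classes"])))
    for name in COMORBIDITY_NAMES:
        rows.append((f"{name.capitalize()}, n (%)", format_count_pct(int(covariates[name].sum()), n)))
    rows.append(("Charlson comorbidity index, mean (SD) (range)", _mean_sd(covariates["cci"], with_range=True)))
    return pd.DataFrame(rows, columns=["variable", "value"])


def render_or_table(
    or_table: pd.DataFrame, covariates: pd.DataFrame, outcome
) -> pd.DataFrame:
    """Factor-table analogue: per covariate, row-percent splits of the
    reference/outcome groups plus crude and adjusted OR (95% CI) strings."""
    y = np.asarray(outcome, dtype=bool)
    rows = []
    for name in or_table.index:
        col = covariates[name]
        if col.dtype == bool or set(np.unique(col)) <= {0, 1}:
            mask = col.astype(bool).to_numpy()
            total = int(mask.sum())
            ref = format_count_pct(int((mask & ~y).sum()), total)
            out = format_count_pct(int((mask & y).sum()), total)
        else:
            ref = _mean_sd(col[~y])
            out = _mean_sd(col[y])
        rows.append(
            (
                name,
                ref,
                out,
                _or_ci(*or_table.loc[name, ["crude_or", "crude_ci_lower", "crude_ci_upper"]]),
                _or_ci(*or_table.loc[name, ["adjusted_or", "adjusted_ci_lower", "adjusted_ci_upper"]]),
            )
        )
    return pd.DataFrame(
        rows, columns=["variable", "reference_group", "outcome_group", "crude_or_ci", "adjusted_or_ci"]
    )


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(
    config: StudyConfig,
    *,
    bundle: ClaimsBundle | None = None,
    sim_config: SimulationConfig | None = None,
    out_dir: Path | str | None = None,
) -> dict:
    """Run the full study and write all artifacts.

    Provide either a validated ``bundle`` or a ``sim_config`` to generate
    one.  Returns a dict of in-memory results (cohort, flow, per-policy
    exposure frames and KM curves, covariates, OR tables, manifest).
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    if bundle is None:
        if sim_config is None:
            raise ValueError("run_pipeline needs a claims bundle or a simulation config")
        bundle, truth = generate(sim_config)
        truth.to_csv(out / "truth.csv", index=False)
    counts["patients"] = bundle.n_patients
    counts["prescriptions"] = len(bundle.prescriptions)
    counts["diagnoses"] = len(bundle.diagnoses)
    counts["visits"] = len(bundle.visits)

    cohort, flow = build_cohort(
        bundle, pre_days=config.pre_index_days, post_days=config.followup_days
    )
    if cohort.empty:
        raise RuntimeError("cohort stage produced no patients")
    cohort_out = cohort.copy()
    cohort_out["index_date"] = cohort_out["index_date"].dt.strftime("%Y%m%d")
    cohort_out.to_csv(out / "cohort.csv", index=False)
    flow.to_frame().to_csv(out / "flow.csv", index=False)
    counts["cohort"] = len(cohort)

    code_map = load_code_map(config.codemap_path)
    covariates = build_covariates(
        cohort, bundle, code_map=code_map, pre_days=config.pre_index_days
    )
    covariates.to_csv(out / "covariates.csv", index=False)

    exposures: dict[int, pd.DataFrame] = {}
    km_curves: dict[int, object] = {}
    for gap in config.gap_policy_days:
        policy = GapPolicy(
            permissible_gap=gap,
            followup_days=config.followup_days,
            pdc_threshold=config.pdc_threshold,
        )
        exp = compute_exposure(cohort, bundle, policy)
        exp.to_csv(out / f"exposure_gap{gap}.csv", index=False)
        km = km_estimate(
            exp["persistence_days"], exp["discontinued"], followup_days=config.followup_days
        )
        km.to_frame().to_csv(out / f"km_curve_gap{gap}.csv", index=False)
        exposures[gap] = exp
        km_curves[gap] = km

    primary = exposures[config.gap_policy_days[0]]
    inc = incidence(primary, followup_days=config.followup_days)
    pd.DataFrame([dataclasses.asdict(inc)]).to_csv(out / "incidence.csv", index=False)

    X = covariates.set_index("patient_id").loc[
        primary["patient_id"], list(MODEL_COVARIATES)
    ]
    vif = check_multicollinearity(X)
    vif.to_csv(out / "vif.csv", index=False)

    nonpersistent = primary["discontinued"].to_numpy().astype(int)
    poor_adherent = (~primary["adherent"].to_numpy()).astype(int)
    or_persistence = fit_or_table(nonpersistent, X.reset_index(drop=True), "non-persistence")
    or_adherence = fit_or_table(poor_adherent, X.reset_index(drop=True), "poor adherence")
    or_persistence.to_csv(out / "or_table_persistence.csv")
    or_adherence.to_csv(out / "or_table_adherence.csv")

    linear_rows = []
    for resp_name, resp in (
        ("pdc", primary["pdc"]),
        ("persistence_days", primary["persistence_days"]),
    ):
        for pred_name in ("age_years", "mean_visit_interval_days"):
            fit = fit_linear(resp, X[pred_name].to_numpy())
            linear_rows.append((resp_name, pred_name, fit.slope, fit.ci_lower, fit.ci_upper, fit.p_value))
    linear = pd.DataFrame(
        linear_rows, columns=["response", "predictor", "slope", "ci_lower", "ci_upper", "p_value"]
    )
    linear.to_csv(out / "linear_fits.csv", index=False)

    table1 = render_table1(covariates)
    table1.to_csv(out / "table1.csv", index=False)
    t2 = render_or_table(or_persistence, X.reset_index(drop=True), nonpersistent)
    t2.to_csv(out / "table2_persistence.csv", index=False)
    t3 = render_or_table(or_adherence, X.reset_index(drop=True), poor_adherent)
    t3.to_csv(out / "table3_adherence.csv", index=False)

    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "gap_policies": list(config.gap_policy_days),
        "row_counts": counts,
        "flow": flow.stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "bundle": bundle,
        "cohort": cohort,
        "flow": flow,
        "covariates": covariates,
        "exposures": exposures,
        "km_curves": km_curves,
        "incidence": inc,
        "vif": vif,
        "or_persistence": or_persistence,
        "or_adherence": or_adherence,
        "linear_fits": linear,
        "manifest": manifest,
    }
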