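"""End-to-end orchestration: bundle -> measures -> classification -> models
-> effectiveness -> report.

`run_all` is a pure function of (inputs, configuration, seed): stage outputs
are written as delimited text/JSON into the output directory together with a
`report.md` that summarizes contrasts per measure per model, elimination
traces, effectiveness estimates and collected warnings, plus a provenance
block (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import paeffect
from paeffect import glmm, io, measures as measures_mod, spatial
from paeffect.constants import DEFAULT_REFERENCE_YEAR, INTENSITIES, LAND_USES
from paeffect.effectiveness import monte_carlo_ci, solve_io, effectiveness as eff_fn
from paeffect.synthetic import SyntheticWorld, WorldConfig, generate_world

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "validate_inputs"]

# Default effectiveness scalars: protected fraction of terrestrial area and
# global average proportional loss of site-level biodiversity vs pristine.
DEFAULT_PROTECTED_FRACTION = 0.154
DEFAULT_GLOBAL_LOSS = 0.136


@dataclass
class RunConfig:
    """Configuration for one full pipeline run.

    Exactly one of ``input_dir`` (an existing bundle) or ``world`` (a
    synthetic-world configuration) must be given.
    """

    input_dir: str | None = None
    world: WorldConfig | None = None
    output_dir: str = "pa_effect_run"
    seed: int = 0
    reference_year: int = DEFAULT_REFERENCE_YEAR
    match_on_intensity: bool = False
    olre: str = "auto"
    include_interaction: bool = True
    include_management: bool = True
    include_size_age: bool = True
    protected_fraction: float = DEFAULT_PROTECTED_FRACTION
    global_loss: float = DEFAULT_GLOBAL_LOSS
    land_use_weights: dict[str, float] | None = None
    n_ci_draws: int = 10_000

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.world is None):
            raise ValueError("exactly one of input_dir / world must be set")


def validate_inputs(source) -> list[dict]:
    """Validate a bundle (directory path or SyntheticWorld) without fitting.

    Returns a machine-readable list of issues, each
    ``{"severity", "code", "message"}``; an empty list means a clean bundle.
    """
    issues: list[dict] = []

    def add(sev, code, msg):
        issues.append({"severity": sev, "code": code, "message": msg})

    if isinstance(source, SyntheticWorld):
        world = source
    else:
        ind = Path(source)
        missing = [
            f
            for f in ("sites.csv", "community.csv", "ranges.csv", "protected_areas.geojson")
            if not (ind / f).exists()
        ]
        if missing:
            add("error", "missing-file", f"bundle lacks {missing}")
            return issues
        world = io.read_bundle(ind)

    sites, comm, ranges = world.sites, world.community, world.ranges
    site_ids = set(sites["site_id"])
    bad_sites = set(comm["site_id"]) - site_ids
    for s in sorted(bad_sites):
        add("error", "referential-integrity", f"community row references unknown site {s!r}")
    bad_taxa = set(comm["taxon_id"]) - set(ranges["taxon_id"])
    if bad_taxa:
        add(
            "warning",
            "missing-range",
            f"{len(bad_taxa)} taxa in the community table have no range entry",
        )
    if (np.abs(sites["longitude"]) > 180).any() or (np.abs(sites["latitude"]) > 90).any():
        add("error", "coordinates", "site coordinates outside valid lon/lat ranges")
    bad_lu = set(sites["land_use"].dropna()) - set(LAND_USES)
    for v in sorted(bad_lu):
        add("error", "land-use-vocabulary", f"unknown land use {v!r}")
    bad_int = set(sites["use_intensity"].dropna()) - set(INTENSITIES)
    for v in sorted(bad_int):
        add("error", "intensity-vocabulary", f"unknown use intensity {v!r}")
    bad_mt = set(comm["measurement_type"]) - {"abundance", "occurrence"}
    for v in sorted(bad_mt):
        add("error", "measurement-type", f"unknown measurement type {v!r}")
    if (comm["measurement"] < 0).any():
        add("error", "negative-measurement", "negative measurements in community table")
    if (ranges["range_km2"] <= 0).any():
        add("error", "range-size", "nonpositive range sizes")
    gj = world.protected_areas
    if gj.get("type") != "FeatureCollection":
        add("error", "geojson", "protected_areas must be a FeatureCollection")
    else:
        for k, f in enumerate(gj.get("features", [])):
            geom = f.get("geometry", {})
            if geom.get("type") not in ("Polygon", "MultiPolygon"):
                add("error", "geojson", f"feature {k}: unsupported geometry type")
                continue
            rings = (
                geom["coordinates"]
                if geom["type"] == "Polygon"
                else [r for poly in geom["coordinates"] for r in poly]
            )
            for ring in rings:
                if ring[0] != ring[-1]:
                    add("error", "geojson", f"feature {k}: unclosed ring")
    return issues


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.records: list[str] = []

    def emit(self, record):
        self.records.append(self.format(record))


def _config_hash(config: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    d = dataclasses.asdict(config)
    d.pop("output_dir", None)  # where results land does not change them
    blob = json.dumps(d, default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _contrast_rows(bundle: dict) -> pd.DataFrame:
    rows = []
    for measure, models in bundle.items():
        for model, entry in models.items():
            for c in entry["contrasts"]:
                rows.append(
                    {
                        "measure": measure,
                        "model": model,
                        "label": c.label,
                        "percent_difference": c.percent_difference,
                        "ci_low": c.ci_low,
                        "ci_high": c.ci_high,
                        "estimate": c.estimate,
                        "se": c.se,
                    }
                )
    return pd.DataFrame(rows)


def _fit_record(entry: dict) -> dict:
    fit = entry["fit"]
    rec = {
        "params": {k: float(v) for k, v in fit.params.items()},
        "se": {k: float(v) for k, v in fit.se.items()},
        "var_components": fit.var_components,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "singular": fit.singular,
        "n_obs": fit.n_obs,
        "n_studies": fit.n_studies,
        "family": fit.family,
        "fixed_terms": list(fit.fixed_terms),
        "random_terms": list(fit.random_terms),
        "dispersion": fit.dispersion,
        "trace": entry["trace"],
    }
    if entry.get("lrt") is not None:
        lrt = entry["lrt"]
        rec["lrt"] = {"chi_square": lrt.chi_square, "df": lrt.df, "p_value": lrt.p_value}
    return rec


def _effectiveness_for_measure(models: dict, weights: dict[str, float],
                               a: float, r: float, n_draws: int, seed: int) -> dict | None:
    entry = models.get("protection_land_use")
    if entry is None or not entry["contrasts"]:
        entry = models.get("protection")
        if entry is None:
            return None
    by_lu: dict[str, tuple[float, float]] = {}
    for c in entry["contrasts"]:
        lu = c.label.split("@")[-1] if "@" in c.label else None
        if lu is None:  # protection-only model: one global ratio
            by_lu = {k: (c.estimate, c.se) for k in weights}
            break
        by_lu[lu] = (c.estimate, c.se)
    usable = {k: w for k, w in weights.items() if k in by_lu and w > 0}
    if not usable:
        return None
    tot = sum(usable.values())
    w_norm = {k: v / tot for k, v in usable.items()}
    if len(usable) < len(weights):
        logger.warning(
            "effectiveness: %d land uses lack estimable contrasts; weights "
            "renormalized over the rest",
            len(weights) - len(usable),
        )
    log_ratios = {k: by_lu[k][0] for k in w_norm}
    log_ses = {k: by_lu[k][1] for k in w_norm}
    rho = float(sum(w_norm[k] * np.exp(log_ratios[k]) for k in w_norm))
    i, o = solve_io(rho, a, r)
    e = eff_fn(i, o)
    out = {
        "rho": rho,
        "i": i,
        "o": o,
        "e": e,
        "weights": w_norm,
        "a": a,
        "r": r,
        "per_land_use_ratio": {k: float(np.exp(v)) for k, v in log_ratios.items()},
    }
    # Restrictive-management scenario from the I-II management contrast.
    scen = None
    mgmt = models.get("management")
    if mgmt is not None:
        for c in mgmt["contrasts"]:
            if c.label.endswith("I-II"):
                scen = (c.estimate, c.se)
    mc = monte_carlo_ci(
        log_ratios,
        log_ses,
        w_norm,
        a,
        r,
        scenario_log_ratio=None if scen is None else scen[0],
        scenario_log_ratio_se=None if scen is None else scen[1],
        n_draws=n_draws,
        seed=seed,
    )
    out["monte_carlo"] = mc
    if scen is not None:
        rho_star = float(np.exp(scen[0]))
        from paeffect.effectiveness import required_area, scenario_effectiveness

        out["rho_scenario"] = rho_star
        out["e_scenario"] = scenario_effectiveness(rho_star, a, r)
        out["required_a"] = required_area(rho, rho_star, a, r)
    return out


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the in-memory report bundle."""
    collector = _WarningCollector()
    logging.getLogger("paeffect").addHandler(collector)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_all_inner(config, out, collector)
    finally:
        logging.getLogger("paeffect").removeHandler(collector)


def _run_all_inner(config: RunConfig, out: Path, collector: _WarningCollector) -> dict:
    stage = "inputs"
    try:
        if config.world is not None:
            world = generate_world(config.world)
            world.write(out / "bundle")
        else:
            world = io.read_bundle(config.input_dir)

        stage = "validate"
        issues = validate_inputs(world)
        errors = [i for i in issues if i["severity"] == "error"]
        if errors:
            raise ValueError(f"{len(errors)} fatal validation issues: {errors[:3]}")

        stage = "measures"
        site_measures = measures_mod.compute_site_measures(
            world.community, world.sites, world.ranges
        )
        site_measures.to_csv(out / "site_measures.csv", index=False)

        stage = "spatial"
        pas = spatial.read_protected_areas(world.protected_areas)
        classified = spatial.assign_protection(
            world.sites, pas, reference_year=config.reference_year
        )
        classified.to_csv(out / "sites_classified.csv", index=False)
        matched = spatial.match_sites_by_land_use(
            classified, on_intensity=config.match_on_intensity
        )
        matched.to_csv(out / "sites_matched.csv", index=False)

        stage = "glmm"
        all_tab = glmm.prepare_analysis_table(site_measures, classified)
        matched_tab = glmm.prepare_analysis_table(
            site_measures, matched
        ) if len(matched) else None
        bundle = glmm.fit_measure_suite(
            all_tab,
            matched_tab,
            olre=config.olre,
            include_interaction=config.include_interaction,
            include_management=config.include_management,
            include_size_age=config.include_size_age,
        )
        fits = {
            m: {k: _fit_record(v) for k, v in models.items()}
            for m, models in bundle.items()
        }
        with open(out / "fits.json", "w") as fh:
            json.dump(fits, fh, indent=1)
        contrasts = _contrast_rows(bundle)
        contrasts.to_csv(out / "contrasts.csv", index=False)
        try:
            _forest_plot(contrasts, out / "contrasts_forest.png")
        except Exception as exc:  # plotting must never sink a run
            logger.warning("forest plot skipped: %s", exc)

        stage = "effectiveness"
        weights = config.land_use_weights
        if weights is None:
            counts = classified["land_use"].value_counts(normalize=True)
            weights = {lu: float(counts.get(lu, 0.0)) for lu in LAND_USES}
        eff = {}
        for measure in ("richness", "abundance"):
            if measure in bundle:
                res = _effectiveness_for_measure(
                    bundle[measure],
                    weights,
                    config.protected_fraction,
                    config.global_loss,
                    config.n_ci_draws,
                    seed=config.seed + 17,
                )
                if res is not None:
                    eff[measure] = res
        with open(out / "effectiveness.json", "w") as fh:
            json.dump(eff, fh, indent=1)

        stage = "report"
        report = _render_report(
            config, world, site_measures, classified, matched, bundle, eff, collector
        )
        (out / "report.md").write_text(report)
        return {
            "world": world,
            "site_measures": site_measures,
            "classified": classified,
            "matched": matched,
            "models": bundle,
            "effectiveness": eff,
            "issues": issues,
            "report_path": str(out / "report.md"),
        }
    except Exception as exc:
        n = None
        try:
            n = len(world.sites)
        except Exception:
            pass
        raise RuntimeError(
            f"pipeline failed in stage {stage!r}"
            + (f" ({n} sites loaded)" if n is not None else "")
            + f": {exc}"
        ) from exc


def _forest_plot(contrasts: pd.DataFrame, path: Path) -> None:
    """Basic forest plot: one panel per measure, percent scale, 95% CIs."""
    if contrasts.empty:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    measures = list(contrasts["measure"].unique())
    fig, axes = plt.subplots(
        1, len(measures), figsize=(4 * len(measures), 5), sharex=False, squeeze=False
    )
    for ax, measure in zip(axes[0], measures):
        sub = contrasts[contrasts["measure"] == measure]
        labels = sub["model"] + " / " + sub["label"]
        y = np.arange(len(sub))[::-1]
        ax.errorbar(
            sub["percent_difference"],
            y,
            xerr=[
                sub["percent_difference"] - sub["ci_low"],
                sub["ci_high"] - sub["percent_difference"],
            ],
            fmt="o",
            capsize=3,
        )
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(y)
        ax.set_yticklabels(labels, fontsize=7)
        ax.set_title(measure)
        ax.set_xlabel("% difference (protected vs not)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _render_report(config, world, site_measures, classified, matched, bundle, eff,
                   collector) -> str:
    lines = []
    lines.append("# Protected-area effect analysis report\n")
    lines.append("## Provenance\n")
    lines.append(f"- package version: {paeffect.__version__}")
    lines.append(f"- config hash: {_config_hash(config)}")
    lines.append(f"- seed: {config.seed}")
    lines.append(f"- reference year: {config.reference_year}\n")
    n_prot = int(classified["protected"].sum())
    lines.append("## Data\n")
    lines.append(f"- studies: {classified['study_id'].nunique()}")
    lines.append(
        f"- sites: {len(classified)} ({n_prot} protected, {len(classified) - n_prot} unprotected)"
    )
    lines.append(f"- matched-sites subset: {len(matched)} sites "
                 f"({matched['study_id'].nunique() if len(matched) else 0} studies)")
    defined = {
        m: int(site_measures[c].notna().sum())
        for m, c in [
            ("richness", "richness"),
            ("abundance", "abundance"),
            ("rarefied_richness", "rarefied_richness"),
            ("endemicity", "endemicity"),
        ]
    }
    lines.append("- defined site measures: " + ", ".join(f"{m}={n}" for m, n in defined.items()) + "\n")

    lines.append("## Contrasts (percent difference, protected vs unprotected)\n")
    for measure, models in bundle.items():
        lines.append(f"### {measure}\n")
        for model, entry in models.items():
            lrt = entry.get("lrt")
            head = f"- **{model}**"
            if lrt is not None:
                head += f" (chi2={lrt.chi_square:.2f}, df={lrt.df}, P={lrt.p_value:.4g})"
            lines.append(head)
            for c in entry["contrasts"]:
                lines.append(
                    f"    - {c.label}: {c.percent_difference:+.1f}% "
                    f"(95% CI {c.ci_low:+.1f} to {c.ci_high:+.1f})"
                )
            dropped = [t["term"] for t in entry["trace"] if t["dropped"]]
            if dropped:
                lines.append(f"    - eliminated terms: {', '.join(dropped)}")
        lines.append("")

    if eff:
        lines.append("## Global effectiveness\n")
        for measure, res in eff.items():
            mc = res["monte_carlo"]["e"]
            lines.append(
                f"- {measure}: rho={res['rho']:.4f}, i={res['i']:.4f}, o={res['o']:.4f}, "
                f"e={100 * res['e']:.1f}% (95% MC CI {100 * mc['lo']:.1f} to {100 * mc['hi']:.1f}%)"
            )
            if "e_scenario" in res:
                lines.append(
                    f"    - restrictive-management scenario: rho*={res['rho_scenario']:.4f}, "
                    f"e*={100 * res['e_scenario']:.1f}%, required area a'="
                    f"{100 * res['required_a']:.1f}% of land"
                )
        lines.append("")

    lines.append("## Warnings\n")
    if collector.records:
        lines.extend(f"- {r}" for r in collector.records)
    else:
        lines.append("- none")
    lines.append("")
    return "\n".join(lines)
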