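"""End-to-end pipeline: simulate -> filter -> detect -> partition ->
ordinate -> permanova -> discriminate -> report.

Every stage writes its outputs before the next begins; the run manifest
records the config echo, per-stage seeds, wall-clock and output checksums,
so two runs with the same config and seed are byte-identical for every
deterministic stage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import build_design
from .discriminant import fit_multiblock_splsda, log2_fold_change
from .flux import partition_series
from .io import (
    sha256_of,
    write_feature_table,
    write_flux_table,
    write_json,
    write_metadata,
    write_nmr_table,
)
from .isotopologue import (
    annotate_clusters,
    cluster_abundance_matrix,
    cluster_isotopologues,
    filter_features,
    summarize_detection,
)
from .multivariate import (
    AbundanceMatrix,
    hierarchical_cluster,
    manhattan_distance,
    median_normalize,
    pareto_scale,
    pcoa,
    permanova,
)
from .synth import (
    DynamicsConfig,
    FluxConfig,
    NoiseConfig,
    generate_feature_table,
    generate_nmr_block,
    generate_species,
    simulate_flux_series,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "filter",
    "detect",
    "partition",
    "ordinate",
    "permanova",
    "discriminate",
    "report",
)


class PipelineError(RuntimeError):
    """A stage-level failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ----------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------
@dataclass
class GeneratorSettings:
    n_species: int = 60
    enrichment: float = 0.524          # litter 13C atom fraction
    replicates: int = 2
    n_nmr_metabolites: int = 45
    nmr_labeled_fraction: float = 0.4
    emission_floor: float = 1e-4
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    flux: FluxConfig = field(default_factory=FluxConfig)


@dataclass
class FilterSettings:
    min_mass: float = 100.0
    max_mass: float = 1200.0
    min_intensity: float = 2e6
    min_snr: float = 3.0


@dataclass
class ClusterSettings:
    rt_tol: float = 0.2
    mass_tol_ppm: float = 5.0
    max_k: int = 100
    min_incorporation: float = 0.02


@dataclass
class PartitionSettings:
    r_litter: float = 0.524


@dataclass
class StatsSettings:
    n_permutations: int = 999
    linkage: str = "average"
    keep_per_block: tuple[int, int] = (20, 6)
    n_components: int = 2
    design_weight: float = 0.1


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "siampeat_run"
    plots: bool = False
    generator: GeneratorSettings = field(default_factory=GeneratorSettings)
    filters: FilterSettings = field(default_factory=FilterSettings)
    clustering: ClusterSettings = field(default_factory=ClusterSettings)
    partition: PartitionSettings = field(default_factory=PartitionSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stats"]["keep_per_block"] = list(self.stats.keep_per_block)
        d["generator"]["flux"]["days"] = list(self.generator.flux.days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        dyn = DynamicsConfig(**gen.pop("dynamics", {}))
        noi = NoiseConfig(**gen.pop("noise", {}))
        flux_d = dict(gen.pop("flux", {}))
        if "days" in flux_d:
            flux_d["days"] = tuple(flux_d["days"])
        flux = FluxConfig(**flux_d)
        stats_d = dict(d.pop("stats", {}))
        if "keep_per_block" in stats_d:
            stats_d["keep_per_block"] = tuple(stats_d["keep_per_block"])
        return cls(
            generator=GeneratorSettings(dynamics=dyn, noise=noi, flux=flux, **gen),
            filters=FilterSettings(**d.pop("filters", {})),
            clustering=ClusterSettings(**d.pop("clustering", {})),
            partition=PartitionSettings(**d.pop("partition", {})),
            stats=StatsSettings(**stats_d),
            **d,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed split from the root seed (< 2**31)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(root_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


# ----------------------------------------------------------------------
# Manifest
# ----------------------------------------------------------------------
@dataclass
class StageRecord:
    name: str
    seconds: float
    rows_in: int | None
    rows_out: int | None
    seed: int | None
    outputs: dict[str, str]  # relative path -> sha256


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[StageRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def checksums(self) -> dict[str, str]:
        out = {}
        for s in self.stages:
            out.update(s.outputs)
        return out

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "stages": [asdict(s) for s in self.stages],
            "warnings": self.warnings,
        }


# ----------------------------------------------------------------------
# Pipeline
# ----------------------------------------------------------------------
def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunManifest:
    """Execute the full pipeline; returns the run manifest.

    Stage-level errors are re-raised as :class:`PipelineError` carrying the
    stage name.  All outputs land under ``outdir`` (defaults to
    ``config.outdir``).
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__)
    results: dict[str, object] = {}

    def run_stage(name, fn, rows_in=None):
        t0 = time.perf_counter()
        seed = stage_seed(config.seed, name)
        try:
            files, rows_out = fn(seed)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        rec = StageRecord(
            name=name,
            seconds=time.perf_counter() - t0,
            rows_in=rows_in,
            rows_out=rows_out,
            seed=seed,
            outputs={str(Path(f).relative_to(out)): sha256_of(f) for f in files},
        )
        manifest.stages.append(rec)
        logger.info(
            "stage %s: rows in=%s out=%s (%.2fs)", name, rows_in, rows_out, rec.seconds
        )
        return rows_out

    gen = config.generator

    # --- simulate -----------------------------------------------------
    def _simulate(seed):
        rng = np.random.default_rng(seed)
        design = build_design(replicates=gen.replicates)
        species = generate_species(
            gen.n_species, enrichment=gen.enrichment, rng=rng
        )
        table, truth = generate_feature_table(
            species,
            design,
            dynamics=gen.dynamics,
            noise=gen.noise,
            seed=int(rng.integers(2**31)),
            emission_floor=gen.emission_floor,
        )
        nmr, nmr_flags = generate_nmr_block(
            gen.n_nmr_metabolites,
            design,
            labeled_fraction=gen.nmr_labeled_fraction,
            dynamics=gen.dynamics,
            seed=int(rng.integers(2**31)),
        )
        flux_obs, flux_truth = simulate_flux_series(
            gen.flux, seed=int(rng.integers(2**31))
        )
        files = [
            write_feature_table(table, out / "feature_table.csv"),
            write_metadata(design, out / "metadata.csv"),
            write_nmr_table(nmr, out / "nmr_table.csv"),
            write_flux_table(flux_obs, out / "flux_table.csv"),
        ]
        truth.feature_map.to_csv(out / "truth_feature_map.csv", index=False)
        truth.species.to_csv(out / "truth_species.csv", index=False)
        flux_truth.components.to_csv(out / "truth_flux.csv", index=False)
        write_json(
            {
                "seed": truth.seed,
                "species": truth.species.to_dict(orient="records"),
                "labeled": truth.labeled.to_dict(),
                "flux_components": flux_truth.components.to_dict(orient="records"),
                "nmr_labeled": nmr_flags.to_dict(),
            },
            out / "ground_truth.json",
        )
        files += [
            out / "truth_feature_map.csv",
            out / "truth_species.csv",
            out / "truth_flux.csv",
            out / "ground_truth.json",
        ]
        results.update(
            design=design, table=table, truth=truth, nmr=nmr, nmr_flags=nmr_flags,
            flux_obs=flux_obs, flux_truth=flux_truth,
        )
        return files, len(table)

    n_rows = run_stage("simulate", _simulate)

    # --- filter -------------------------------------------------------
    def _filter(seed):
        f = config.filters
        filtered = filter_features(
            results["table"],
            min_mass=f.min_mass,
            max_mass=f.max_mass,
            min_intensity=f.min_intensity,
            min_snr=f.min_snr,
        )
        results["filtered"] = filtered
        return [write_feature_table(filtered, out / "filtered_table.csv")], len(filtered)

    n_filtered = run_stage("filter", _filter, rows_in=n_rows)

    # --- detect -------------------------------------------------------
    def _detect(seed):
        filtered = results["filtered"]
        if len(filtered) == 0:
            raise PipelineError("detect", "empty feature set after filtering")
        c = config.clustering
        clusters = cluster_isotopologues(
            filtered, rt_tol=c.rt_tol, mass_tol_ppm=c.mass_tol_ppm, max_k=c.max_k
        )
        labeled_samples = [
            s.sample_id for s in results["design"] if s.label_status == "labeled"
        ]
        control_samples = [
            s.sample_id for s in results["design"] if s.label_status == "unlabeled"
        ]
        annotate_clusters(
            clusters,
            min_incorporation=c.min_incorporation,
            sample_ids=labeled_samples,
            control_sample_ids=control_samples,
        )
        summary = summarize_detection(clusters)
        results["clusters"] = clusters
        results["detection_summary"] = summary
        rows = pd.DataFrame(
            [
                {
                    "cluster_id": cl.cluster_id,
                    "base_feature": cl.base_feature.feature_id,
                    "n_members": len(cl.members),
                    "max_k": cl.max_k,
                    "n_carbon_est": cl.n_carbon_est,
                    "enrichment_at_pct": cl.enrichment_at_pct,
                    "diagnostic_ratio": cl.diagnostic_ratio,
                    "label_call": cl.label_call,
                }
                for cl in clusters
            ]
        )
        rows.to_csv(out / "clusters.csv", index=False)
        write_json(rows.to_dict(orient="records"), out / "clusters.json")
        write_json(summary.to_dict(), out / "detection_summary.json")
        return (
            [out / "clusters.csv", out / "clusters.json", out / "detection_summary.json"],
            len(clusters),
        )

    run_stage("detect", _detect, rows_in=n_filtered)

    # --- partition ----------------------------------------------------
    def _partition(seed):
        part = partition_series(results["flux_obs"], r_litter=config.partition.r_litter)
        results["flux_partition"] = part
        part.per_jar_day.to_csv(out / "partition_per_day.csv", index=False)
        part.cumulative.to_csv(out / "partition_cumulative.csv", index=False)
        write_json(
            {
                "unit": part.unit,
                "r_litter": part.r_litter,
                "skipped_days": part.skipped_days,
                "per_jar_day": part.per_jar_day.to_dict(orient="records"),
                "cumulative": part.cumulative.to_dict(orient="records"),
            },
            out / "partition.json",
        )
        return (
            [
                out / "partition_per_day.csv",
                out / "partition_cumulative.csv",
                out / "partition.json",
            ],
            len(part.per_jar_day),
        )

    run_stage("partition", _partition, rows_in=len(results["flux_obs"]))

    # --- ordinate -----------------------------------------------------
    def _ordinate(seed):
        # compound-level abundances: labeled/unlabeled samples are
        # replicates once isotopologue families are collapsed
        sample_ids = [s.sample_id for s in results["design"]]
        compound = cluster_abundance_matrix(results["clusters"], sample_ids)
        mat = AbundanceMatrix(values=compound, design=results["design"])
        scaled = pareto_scale(median_normalize(mat))
        results["scaled"] = scaled
        dist = manhattan_distance(scaled)
        results["distance"] = dist
        ord_res = pcoa(dist)
        results["ordination"] = ord_res
        Z = hierarchical_cluster(dist, linkage=config.stats.linkage)
        results["dendrogram"] = Z
        ord_res.coordinates.to_csv(out / "pcoa_coordinates.csv")
        pd.DataFrame(
            {
                "eigenvalue": ord_res.eigenvalues,
            }
        ).to_csv(out / "pcoa_eigenvalues.csv", index=False)
        pd.DataFrame(
            Z, columns=["left", "right", "height", "size"]
        ).to_csv(out / "dendrogram.csv", index=False)
        files = [
            out / "pcoa_coordinates.csv",
            out / "pcoa_eigenvalues.csv",
            out / "dendrogram.csv",
        ]
        if config.plots:
            from .plotting import plot_flux_partition, plot_ordination

            files.append(
                plot_ordination(ord_res, results["design"], out / "pcoa.png")
            )
            files.append(
                plot_flux_partition(
                    results["flux_partition"], out / "flux_partition.png"
                )
            )
        return files, len(dist)

    run_stage("ordinate", _ordinate, rows_in=n_filtered)

    # --- permanova ----------------------------------------------------
    def _permanova(seed):
        dist = results["distance"]
        design = results["design"]
        rows = []
        perms = config.stats.n_permutations
        rng = np.random.default_rng(seed)
        for factor, labels in (
            ("treatment", [s.treatment for s in design]),
            ("timepoint", [s.timepoint for s in design]),
        ):
            res = permanova(
                dist,
                labels,
                n_permutations=perms,
                seed=int(rng.integers(2**31)),
                grouping_name=factor,
            )
            rows.append(
                {
                    "factor": factor,
                    "pseudo_f": res.pseudo_f,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                }
            )
        df = pd.DataFrame(rows)
        results["permanova"] = df
        df.to_csv(out / "permanova.csv", index=False)
        return [out / "permanova.csv"], len(df)

    run_stage("permanova", _permanova)

    # --- discriminate -------------------------------------------------
    def _discriminate(seed):
        design = results["design"]
        keep_samples = [s for s in design if s.treatment in ("PO", "PL")]
        ids = [s.sample_id for s in keep_samples]
        classes = [s.treatment for s in keep_samples]

        compound = cluster_abundance_matrix(results["clusters"], ids)
        ms = AbundanceMatrix(values=compound)
        ms_scaled = pareto_scale(median_normalize(ms))

        nmr = results["nmr"]
        nmr_vals = nmr.set_index("metabolite_id")[ids]
        nmr_scaled = pareto_scale(median_normalize(AbundanceMatrix(values=nmr_vals)))

        keep = config.stats.keep_per_block
        fit = fit_multiblock_splsda(
            {"ms": ms_scaled, "nmr": nmr_scaled},
            classes,
            keep_per_block={"ms": keep[0], "nmr": keep[1]},
            n_components=config.stats.n_components,
            design_weight=config.stats.design_weight,
            seed=seed,
        )
        results["discriminant"] = fit
        ranked = fit.rank_discriminants(1)
        results["discriminants_ranked"] = ranked
        fc = log2_fold_change(
            median_normalize(AbundanceMatrix(values=ms.values.copy())),
            design=keep_samples,
        )
        results["fold_change"] = fc
        for name in fit.model.block_names:
            fit.loadings[name].to_csv(out / f"splsda_loadings_{name}.csv")
            fit.scores[name].to_csv(out / f"splsda_scores_{name}.csv")
        ranked.to_csv(out / "discriminant_features.csv", index=False)
        fc.to_csv(out / "fold_change.csv", index=False)
        files = [
            out / f"splsda_loadings_{n}.csv" for n in fit.model.block_names
        ] + [
            out / f"splsda_scores_{n}.csv" for n in fit.model.block_names
        ] + [out / "discriminant_features.csv", out / "fold_change.csv"]
        return files, len(ranked)

    run_stage("discriminate", _discriminate)

    # --- report -------------------------------------------------------
    def _report(seed):
        files = write_report(results, out)
        return files, None

    run_stage("report", _report)

    write_json(manifest.to_dict(), out / "manifest.json")
    return manifest


# ----------------------------------------------------------------------
# Report
# ----------------------------------------------------------------------
def write_report(results: dict, outdir: str | Path) -> list[Path]:
    """Render a human-readable markdown report plus its JSON twin.

    Sections for stages that did not run are marked "not run".
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not results:
        raise ValueError("no stage results to report")
    lines = ["# SIAM pipeline report", ""]
    twin: dict = {}

    summary = results.get("detection_summary")
    lines.append("## Detection summary")
    if summary is None:
        lines.append("not run")
    else:
        d = summary.to_dict()
        twin["detection_summary"] = d
        lines.append(
            f"- features (clusters): {d['n_features_total']}; labeled: "
            f"{d['n_labeled']} ({d['pct_labeled']:.2f}%)"
        )
        for cat, v in d["categories"].items():
            lines.append(f"- {cat}: {v['count']} ({v['pct']:.2f}%)")
    lines.append("")

    part = results.get("flux_partition")
    lines.append("## Flux partition and priming")
    if part is None:
        lines.append("not run")
    else:
        per = part.per_jar_day
        twin["flux_partition"] = {
            "per_jar_day": per.to_dict(orient="records"),
            "cumulative": part.cumulative.to_dict(orient="records"),
            "unit": part.unit,
        }
        lines.append(f"unit: {part.unit}")
        by_day = per.groupby("day")[["litter_flux", "peat_flux", "priming_flux"]].mean()
        lines.append("")
        lines.append("| day | litter | peat | priming |")
        lines.append("|----:|-------:|-----:|--------:|")
        for day, row in by_day.iterrows():
            lines.append(
                f"| {day:g} | {row['litter_flux']:.3f} | {row['peat_flux']:.3f} "
                f"| {row['priming_flux']:.3f} |"
            )
    lines.append("")

    ordn = results.get("ordination")
    lines.append("## Ordination (PCoA, Manhattan distances)")
    if ordn is None:
        lines.append("not run")
    else:
        twin["ordination"] = {
            "coordinates": ordn.coordinates.round(6).to_dict(orient="index"),
            "proportion_explained": list(ordn.proportion_explained[:5]),
        }
        for i, p in enumerate(ordn.proportion_explained[:3]):
            lines.append(f"- PCo{i + 1}: {100 * p:.1f}% of (positive-eigenvalue) variance")
    lines.append("")

    perm = results.get("permanova")
    lines.append("## PERMANOVA")
    if perm is None:
        lines.append("not run")
    else:
        twin["permanova"] = perm.to_dict(orient="records")
        lines.append("| factor | pseudo-F | p |")
        lines.append("|--------|---------:|---:|")
        for _, r in perm.iterrows():
            lines.append(f"| {r['factor']} | {r['pseudo_f']:.3f} | {r['p_value']:.4f} |")
    lines.append("")

    fit = results.get("discriminant")
    lines.append("## Discriminant features (multiblock sPLS-DA, variate 1)")
    if fit is None:
        lines.append("not run")
    else:
        ranked = results.get("discriminants_ranked")
        twin["discriminant"] = {
            "explained_variance": fit.explained_variance,
            "top_features": ranked.head(10).to_dict(orient="records")
            if ranked is not None
            else [],
        }
        for name, ev in fit.explained_variance.items():
            lines.append(
                f"- block {name}: explained variance "
                + ", ".join(f"{100 * v:.1f}%" for v in ev)
            )
        if ranked is not None and len(ranked):
            lines.append("")
            lines.append("| rank | feature | block | loading |")
            lines.append("|----:|---------|-------|--------:|")
            for i, r in ranked.head(10).iterrows():
                lines.append(
                    f"| {i + 1} | {r['feature_id']} | {r['block']} | {r['loading']:.4f} |"
                )
    lines.append("")

    fc = results.get("fold_change")
    lines.append("## Fold-change trajectories (log2 vs PO at T0)")
    if fc is None:
        lines.append("not run")
    else:
        twin["fold_change_n_rows"] = len(fc)
        lines.append(f"{len(fc)} feature x group rows written to fold_change.csv")
    lines.append("")

    report_md = out / "report.md"
    report_md.write_text("\n".join(lines), encoding="utf-8")
    report_json = write_json(twin, out / "report.json")
    return [report_md, report_json]
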