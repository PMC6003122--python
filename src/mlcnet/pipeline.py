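"""End-to-end pipeline: cohort -> reports, networks, comparisons, manifest.

One config drives everything; reruns with the same config and seed produce
byte-identical outputs, verified through the sha256 checksums recorded in
the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortTable, CohortValidationError, read_cohort, write_cohort
from .correlation import SpearmanCorrelation
from .group_tests import GroupComparison
from .metrics import comparison_frame, metrics_report
from .network import build_network, export_network
from .simulate import (CohortSpec, default_study_spec, generate_cohort,
                       spec_from_yaml, write_ground_truth)
from .stratify import StratificationRule, stratified_networks
from .subsample import SubsampleConfig, equalized_density_gap

log = logging.getLogger("mlcnet")

STAGES = ("cohort", "bivariate", "correlation", "network", "metrics",
          "stratify", "subsample")


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    Either ``values``/``meta`` input paths or a synthetic spec (path or
    ``"default"``) with a mandatory seed.
    """

    out_dir: Path
    values: Path | None = None
    meta: Path | None = None
    synthetic_spec: str | None = None
    seed: int | None = None
    p_threshold: float = 0.01
    alpha: float = 0.05
    min_n: int = 5
    subsample_m: int = 25
    subsample_B: int = 1000
    rules: tuple[StratificationRule, ...] = ()
    subsample_rule: str | None = None  # rule whose strata get the equal-n control
    formats: tuple[str, ...] = ("graphml", "edge_table")
    overwrite: bool = False

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if not (0 < self.p_threshold < 1):
            raise CohortValidationError(
                f"p_threshold must be in (0, 1), got {self.p_threshold}"
            )
        if not (0 < self.alpha < 1):
            raise CohortValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_n < 3:
            raise CohortValidationError("min_n must be >= 3")
        synthetic = self.synthetic_spec is not None
        if synthetic == (self.values is not None):
            raise CohortValidationError(
                "config must give exactly one of (values, meta) or synthetic_spec"
            )
        if synthetic and self.seed is None:
            raise CohortValidationError(
                "seed is mandatory when the synthetic stage is enabled"
            )
        if not synthetic:
            for p in (self.values, self.meta):
                if p is None or not Path(p).exists():
                    raise CohortValidationError(f"input file not found: {p}")
        if self.synthetic_spec not in (None, "default"):
            if not Path(self.synthetic_spec).exists():
                raise CohortValidationError(
                    f"synthetic spec file not found: {self.synthetic_spec}"
                )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update(overrides)
        rules = tuple(
            StratificationRule(
                name=r["name"],
                groups=frozenset(r["groups"]) if "groups" in r else None,
                variable=r.get("variable"),
                cut=r.get("cut"),
                side=r.get("side", "ge"),
            )
            for r in doc.pop("rules", [])
        )
        sub = doc.pop("subsample", {}) or {}
        return cls(
            out_dir=doc.pop("out_dir"),
            values=doc.pop("values", None),
            meta=doc.pop("meta", None),
            synthetic_spec=doc.pop("synthetic_spec", None),
            seed=doc.pop("seed", None),
            p_threshold=doc.pop("p_threshold", 0.01),
            alpha=doc.pop("alpha", 0.05),
            min_n=doc.pop("min_n", 5),
            subsample_m=sub.get("m", 25),
            subsample_B=sub.get("B", 1000),
            subsample_rule=sub.get("rule"),
            rules=rules,
            formats=tuple(doc.pop("formats", ("graphml", "edge_table"))),
            overwrite=doc.pop("overwrite", False),
        )

    def echo(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "values": str(self.values) if self.values else None,
            "meta": str(self.meta) if self.meta else None,
            "synthetic_spec": self.synthetic_spec,
            "seed": self.seed,
            "p_threshold": self.p_threshold,
            "alpha": self.alpha,
            "min_n": self.min_n,
            "subsample": {"m": self.subsample_m, "B": self.subsample_B,
                          "rule": self.subsample_rule},
            "rules": [
                {
                    "name": r.name,
                    "groups": sorted(r.groups) if r.groups else None,
                    "variable": r.variable,
                    "cut": r.cut,
                }
                for r in self.rules
            ],
            "formats": list(self.formats),
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _prepare_out_dir(out_dir: Path, overwrite: bool) -> None:
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out_dir} is not empty; pass overwrite to proceed"
        )
    out_dir.mkdir(parents=True, exist_ok=True)


def simulate_to_dir(spec: CohortSpec, out_dir, overwrite: bool = False) -> dict:
    """Write the cohort CSV pair plus the ground-truth edge list for a spec."""
    out_dir = Path(out_dir)
    _prepare_out_dir(out_dir, overwrite)
    cohort, truth = generate_cohort(spec)
    values_path = out_dir / "cohort_values.csv"
    meta_path = out_dir / "cohort_meta.csv"
    truth_path = out_dir / "ground_truth.csv"
    write_cohort(cohort, values_path, meta_path)
    write_ground_truth(truth, truth_path)
    return {
        "group_sizes": cohort.group_sizes(),
        "n_subjects": cohort.n_subjects,
        "n_variables": cohort.n_variables,
        "files": [str(values_path), str(meta_path), str(truth_path)],
    }


def _load_spec(config: PipelineConfig) -> CohortSpec:
    if config.synthetic_spec == "default":
        return default_study_spec(config.seed)
    spec = spec_from_yaml(config.synthetic_spec)
    # the pipeline seed overrides the file's seed so one flag controls a run
    return CohortSpec(
        group_sizes=spec.group_sizes, variables=spec.variables,
        blocks=spec.blocks, noise_df=spec.noise_df,
        missing_rate=spec.missing_rate, seed=config.seed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    out = config.out_dir
    _prepare_out_dir(out, config.overwrite)
    manifest: dict = {
        "package": "mlcnet",
        "version": __version__,
        "config": config.echo(),
        "stages": {},
    }
    outputs: dict[str, list[Path]] = {}
    t0 = time.monotonic()

    def record(stage: str, files: list[Path]) -> None:
        outputs[stage] = files
        manifest["stages"][stage] = {
            "outputs": {
                str(f.relative_to(out)): _sha256(f) for f in sorted(files)
            }
        }
        log.info("stage %-11s done (%.2fs, %d files)", stage,
                 time.monotonic() - t0, len(files))

    try:
        # 1 — cohort (simulate or ingest)
        if config.synthetic_spec is not None:
            spec = _load_spec(config)
            cohort, truth = generate_cohort(spec)
            files = [out / "cohort_values.csv", out / "cohort_meta.csv",
                     out / "ground_truth.csv"]
            write_cohort(cohort, files[0], files[1])
            write_ground_truth(truth, files[2])
        else:
            cohort = read_cohort(config.values, config.meta)
            files = [out / "cohort_values.csv", out / "cohort_meta.csv"]
            write_cohort(cohort, files[0], files[1])
        record("cohort", files)

        # 2 — bivariate group comparisons
        biv = GroupComparison(alpha=config.alpha).fit(cohort)
        biv_path = out / "bivariate_report.csv"
        biv.to_frame(levels=cohort.levels).to_csv(biv_path, index=False)
        record("bivariate", [biv_path])

        # 3 — pooled correlation matrix
        corr = SpearmanCorrelation(min_n=config.min_n).fit(cohort)
        corr_path = out / "correlations.csv"
        corr.to_long().to_csv(corr_path, index=False)
        record("correlation", [corr_path])

        # 4 — pooled network exports
        net = build_network(corr, cohort.levels, config.p_threshold)
        net_files = []
        for fmt in config.formats:
            ext = {"graphml": "graphml", "sif": "sif", "edge_table": "csv"}[fmt]
            net_files.append(
                export_network(net, out / f"network_pooled.{ext}", fmt)
            )
        record("network", net_files)

        # 5 — pooled metrics
        met_path = out / "metrics_pooled.csv"
        pd.DataFrame([{"network": "pooled", **metrics_report(net)}]).to_csv(
            met_path, index=False
        )
        record("metrics", [met_path])

        # 6 — stratified networks and comparisons
        analysis = stratified_networks(
            cohort, config.rules, p_threshold=config.p_threshold,
            min_n=config.min_n,
        )
        strat_files = []
        met_rows, comp_items = [], []
        for rule_name, nets in analysis.networks:
            for label, sn in nets:
                for fmt in config.formats:
                    ext = {"graphml": "graphml", "sif": "sif",
                           "edge_table": "csv"}[fmt]
                    strat_files.append(export_network(
                        sn, out / f"network_{rule_name}_{label}.{ext}", fmt
                    ))
                met_rows.append(
                    {"network": f"{rule_name}/{label}", **metrics_report(sn)}
                )
        for rule_name, comps in analysis.comparisons:
            for la, lb, c in comps:
                comp_items.append((f"{rule_name}/{la}", f"{rule_name}/{lb}", c))
        if met_rows:
            p = out / "metrics_strata.csv"
            pd.DataFrame(met_rows).to_csv(p, index=False)
            strat_files.append(p)
        if comp_items:
            p = out / "comparisons.csv"
            comparison_frame(comp_items).to_csv(p, index=False)
            strat_files.append(p)
        record("stratify", strat_files)

        # 7 — equal-n subsampling control on the chosen rule's first two strata
        sub_files = []
        sub_rule = None
        if config.subsample_rule is not None:
            sub_rule = next(
                (r for r in config.rules if r.name == config.subsample_rule),
                None,
            )
            if sub_rule is None:
                raise CohortValidationError(
                    f"subsample rule {config.subsample_rule!r} not among rules"
                )
        elif config.rules:
            sub_rule = next((r for r in config.rules if r.is_group_rule),
                            config.rules[0])
        if sub_rule is not None:
            split = dict(analysis.splits)[sub_rule.name]
            labels = split.labels()
            sub_cfg = SubsampleConfig(
                m=config.subsample_m, n_replicates=config.subsample_B,
                seed=config.seed if config.seed is not None else 0,
            )
            gap = equalized_density_gap(
                split[labels[0]], split[labels[1]], sub_cfg,
                p_threshold=config.p_threshold, min_n=config.min_n,
            )
            p = out / "subsample_gap.csv"
            pd.DataFrame([{
                "rule": sub_rule.name,
                "stratum_a": labels[0], "stratum_b": labels[1],
                "raw_density_a": gap.raw_density_a,
                "raw_density_b": gap.raw_density_b,
                "equalized_density_a": gap.density_a,
                "equalized_density_b": gap.density_b,
                "equalized_gap": gap.gap,
                "m": gap.m, "B": gap.n_replicates,
            }]).to_csv(p, index=False)
            sub_files.append(p)
        record("subsample", sub_files)
    except Exception as exc:
        manifest["failed_stage"] = next(
            (s for s in STAGES if s not in manifest["stages"]), "unknown"
        )
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        raise RuntimeError(
            f"pipeline failed at stage {manifest['failed_stage']!r}: {exc}"
        ) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
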