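"""End-to-end runner: simulate -> fit -> roistats -> network -> report.

A YAML config drives the whole chain.  Every stage writes plain-text outputs
into the run directory and is recorded in a manifest (config hash, seeds,
per-stage file list with checksums) sufficient to re-execute the run
byte-identically.  ``run_all`` supports resuming: a stage is re-executed when
any of its outputs is missing or an upstream stage was re-executed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import RegionAtlas, make_atlas
from .cohort import (CohortSpec, simulate_bpnd, simulate_cohort_tacs,
                     simulate_covariates, subjects_frame)
from .group_stats import anova_two_way, hedonic_long_table, region_set_comparisons
from .kinetics import BasisFitter, FrameSchedule, default_schedule
from .network import run_network_comparison
from . import io as mio
from .cohort import SubjectRecord

__all__ = ["ConfigError", "RunConfig", "RunManifest", "validate_config",
           "run_all", "write_report", "fit_tac_directory", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "roistats", "network", "report")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    seed: int
    output_dir: str
    cohort: CohortSpec
    atlas_n_regions: int = 125
    schedule_path: str | None = None      # None -> packaged 26-frame schedule
    reference: str = "occipital"
    stats_variant: str = "pooled"
    stats_alpha: float = 0.05
    network_permutations: int = 5000
    network_alphas: tuple[float, ...] = (0.05, 0.001)
    network_direction: str = "greater"
    network_seed: int | None = None       # None -> derived from seed

    def canonical_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = asdict(self.cohort)
        d["network_alphas"] = list(self.network_alphas)
        if d["cohort"]["covariance_regions"] is not None:
            d["cohort"]["covariance_regions"] = list(d["cohort"]["covariance_regions"])
        d["cohort"]["striatal_means"] = list(d["cohort"]["striatal_means"])
        d["cohort"]["covariance_strength"] = list(d["cohort"]["covariance_strength"])
        return d

    def config_hash(self) -> str:
        d = self.canonical_dict()
        d.pop("output_dir")  # a storage location, not a scientific parameter
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @property
    def effective_network_seed(self) -> int:
        return self.network_seed if self.network_seed is not None else (self.seed + 1) % (2**31)

    def schedule(self) -> FrameSchedule:
        if self.schedule_path is None:
            return default_schedule()
        return FrameSchedule.from_json(self.schedule_path)


def _build_config(raw: dict, base_dir: Path) -> RunConfig:
    errors = []
    if "seed" not in raw:
        errors.append("missing field: seed")
    if "output_dir" not in raw:
        errors.append("missing field: output_dir")
    cohort_raw = dict(raw.get("cohort", {}))
    cohort_raw.setdefault("seed", raw.get("seed", 0))
    if "striatal_means" in cohort_raw:
        cohort_raw["striatal_means"] = tuple(cohort_raw["striatal_means"])
    if "covariance_strength" in cohort_raw:
        cohort_raw["covariance_strength"] = tuple(cohort_raw["covariance_strength"])
    if cohort_raw.get("covariance_regions") is not None:
        cohort_raw["covariance_regions"] = tuple(cohort_raw["covariance_regions"])
    try:
        cohort = CohortSpec(**cohort_raw)
        cohort.validate()
    except (TypeError, ValueError) as exc:
        errors.append(f"cohort: {exc}")
        cohort = CohortSpec()
    net = raw.get("network", {})
    stats = raw.get("stats", {})
    alphas = tuple(net.get("alphas", (0.05, 0.001)))
    for a in list(alphas) + [stats.get("alpha", 0.05)]:
        if not (0.0 < a < 1.0):
            errors.append(f"alpha out of range (0, 1): {a}")
    permutations = int(net.get("permutations", 5000))
    if permutations < 100:
        errors.append(f"network.permutations must be >= 100, got {permutations}")
    direction = net.get("direction", "greater")
    if direction not in ("greater", "two-sided"):
        errors.append(f"network.direction must be 'greater' or 'two-sided', got {direction!r}")
    variant = stats.get("test_variant", "pooled")
    if variant not in ("pooled", "welch"):
        errors.append(f"stats.test_variant must be 'pooled' or 'welch', got {variant!r}")
    schedule_path = raw.get("schedule")
    if schedule_path in (None, "default"):
        schedule_path = None
    else:
        schedule_path = str((base_dir / schedule_path).resolve())
        if not Path(schedule_path).exists():
            errors.append(f"schedule file not found: {schedule_path}")
    if errors:
        raise ConfigError("; ".join(errors))
    out_dir = raw["output_dir"]
    if not Path(out_dir).is_absolute():
        out_dir = str((base_dir / out_dir).resolve())
    return RunConfig(
        seed=int(raw["seed"]),
        output_dir=out_dir,
        cohort=cohort,
        atlas_n_regions=int(raw.get("atlas", {}).get("n_regions", 125)),
        schedule_path=schedule_path,
        reference=raw.get("fit", {}).get("reference", "occipital"),
        stats_variant=variant,
        stats_alpha=float(stats.get("alpha", 0.05)),
        network_permutations=permutations,
        network_alphas=alphas,
        network_direction=direction,
        network_seed=net.get("seed"),
    )


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return _build_config(raw, path.parent)


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    version: str
    stages: dict[str, list[str]] = field(default_factory=dict)     # stage -> relpaths
    checksums: dict[str, str] = field(default_factory=dict)        # relpath -> sha256
    timestamps: dict[str, str] = field(default_factory=dict)

    @property
    def manifest_hash(self) -> str:
        blob = json.dumps(
            {"config": self.config_hash, "files": self.checksums, "seeds": self.seeds},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()

    def all_files(self) -> list[str]:
        return sorted({f for files in self.stages.values() for f in files})

    def to_json(self, path) -> None:
        d = asdict(self)
        d["manifest_hash"] = self.manifest_hash
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        d.pop("manifest_hash", None)
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def _stage_outputs(config: RunConfig) -> dict[str, list[str]]:
    n_sub = config.cohort.n_patients + config.cohort.n_controls
    sim = ["atlas.json", "schedule.json", "subjects.csv", "provenance.json"]
    # subject ids are deterministic (P01.., C01..)
    ids = [f"P{i + 1:02d}" for i in range(config.cohort.n_patients)] + \
          [f"C{i + 1:02d}" for i in range(config.cohort.n_controls)]
    sim += [f"tacs/sub-{s}_tacs.tsv" for s in ids]
    net = ["edges.csv", "components.json", "zmatrix_patient.csv", "zmatrix_control.csv"]
    return {
        "simulate": sim,
        "fit": ["bpnd.csv"],
        "roistats": ["comparisons.csv", "anova.csv"],
        "network": net,
        "report": ["report.txt"],
    }


def _stage_simulate(config: RunConfig, out: Path) -> None:
    atlas = make_atlas(config.atlas_n_regions)
    sched = config.schedule()
    records = simulate_bpnd(config.cohort, atlas)
    simulate_covariates(records, config.cohort, atlas=atlas)
    atlas.to_json(out / "atlas.json")
    sched.to_json(out / "schedule.json")
    mio.write_subjects_csv(out / "subjects.csv", subjects_frame(records))
    tacs = simulate_cohort_tacs(records, config.cohort, sched)
    for sid, sub_tacs in tacs.items():
        mio.write_subject_tacs(out / "tacs", sid, sub_tacs)
    prov = config.canonical_dict()
    prov.pop("output_dir")  # implied by the file's own location
    with open(out / "provenance.json", "w") as fh:
        json.dump({"config": prov, "seed": config.seed,
                   "version": __version__}, fh, indent=1, sort_keys=True)


def fit_tac_directory(tacs_dir, reference: str = "occipital",
                      schedule: FrameSchedule | None = None) -> pd.DataFrame:
    """Fit SRTM to every region of every subject TAC file in a directory.

    Returns a subjects x regions BP_ND matrix (the reference region is not a
    column of the result).  The schedule read from each file must match the
    one supplied, when given.
    """
    tacs_dir = Path(tacs_dir)
    paths = sorted(tacs_dir.glob("sub-*_tacs.tsv"))
    if not paths:
        raise FileNotFoundError(f"no subject TAC files under {tacs_dir}")
    rows = {}
    for path in paths:
        sid, sched, tacs = mio.read_subject_tacs(path)
        if schedule is not None and not np.allclose(sched.frame_starts,
                                                    schedule.frame_starts):
            raise ValueError(f"{path.name}: schedule does not match the supplied one")
        if reference not in tacs:
            raise ValueError(f"{path.name}: reference region {reference!r} not present")
        fitter = BasisFitter(tacs[reference])
        rows[sid] = {
            region: fitter.fit(tac).params.bp_nd
            for region, tac in tacs.items() if region != reference
        }
    return pd.DataFrame(rows).T.sort_index()


def _stage_fit(config: RunConfig, out: Path) -> None:
    bpnd = fit_tac_directory(out / "tacs", reference=config.reference,
                             schedule=config.schedule())
    # keep the simulated subject order (patients first) for readability
    subjects = mio.read_subjects_csv(out / "subjects.csv")
    mio.write_bpnd_csv(out / "bpnd.csv", bpnd.reindex(subjects.index))


def _records_from_outputs(out: Path) -> tuple[list[SubjectRecord], RegionAtlas, pd.Series]:
    atlas = RegionAtlas.from_json(out / "atlas.json")
    bpnd = mio.read_bpnd_csv(out / "bpnd.csv")
    subjects = mio.read_subjects_csv(out / "subjects.csv")
    records = [
        SubjectRecord(subject_id=sid, group=subjects.loc[sid, "group"],
                      regional_bpnd=bpnd.loc[sid].reindex(atlas.region_names))
        for sid in bpnd.index
    ]
    return records, atlas, subjects["group"]


def _stage_roistats(config: RunConfig, out: Path) -> None:
    records, atlas, _ = _records_from_outputs(out)
    comps = region_set_comparisons(records, atlas, variant=config.stats_variant)
    comps.to_csv(out / "comparisons.csv", index_label="region_set", float_format="%.10g")
    anova = anova_two_way(hedonic_long_table(records, atlas))
    anova.to_frame().to_csv(out / "anova.csv", index_label="factor", float_format="%.10g")


def _stage_network(config: RunConfig, out: Path) -> None:
    _, atlas, groups = _records_from_outputs(out)
    bpnd = mio.read_bpnd_csv(out / "bpnd.csv")[atlas.region_names]
    rep = run_network_comparison(
        bpnd, groups, alphas=config.network_alphas,
        n_permutations=config.network_permutations,
        seed=config.effective_network_seed, direction=config.network_direction,
    )
    rep.edge_stats.edges_frame().to_csv(out / "edges.csv", index=False, float_format="%.10g")
    comp_doc = {
        str(alpha): {
            "n_significant_edges": rep.n_significant_edges[alpha],
            "components": [
                {"regions": c.regions, "edges": [list(e) for e in c.edges],
                 "n_edges": c.n_edges, "p_corrected": c.p_corrected}
                for c in rep.nbs[alpha].components
            ],
        }
        for alpha in config.network_alphas
    }
    comp_doc["n_edges_total"] = rep.n_edges
    with open(out / "components.json", "w") as fh:
        json.dump(comp_doc, fh, indent=1, sort_keys=True)
    rep.edge_stats.z_a.to_csv(out / "zmatrix_patient.csv", float_format="%.10g")
    rep.edge_stats.z_b.to_csv(out / "zmatrix_control.csv", float_format="%.10g")


def _stage_report(config: RunConfig, out: Path) -> None:
    text = _render_report(config, out)
    (out / "report.txt").write_text(text)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "roistats": _stage_roistats,
    "network": _stage_network,
    "report": _stage_report,
}


def run_all(config: RunConfig, resume: bool = False) -> RunManifest:
    """Run every stage; returns the manifest (also written to manifest.json).

    With ``resume=True``, stages whose outputs all exist are skipped unless
    an upstream stage was re-executed.  Fails fast with a stage-scoped error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = _stage_outputs(config)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seeds={"cohort": config.cohort.seed, "network": config.effective_network_seed},
        version=__version__,
    )
    upstream_ran = False
    for stage in STAGES:
        paths = [out / rel for rel in outputs[stage]]
        have_all = all(p.exists() for p in paths)
        if resume and have_all and not upstream_ran:
            log.info("stage %s: outputs present, skipped (resume)", stage)
        else:
            log.info("stage %s: running", stage)
            t0 = time.time()
            try:
                _STAGE_FUNCS[stage](config, out)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1f s", stage, time.time() - t0)
            upstream_ran = True
        manifest.stages[stage] = outputs[stage]
        manifest.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")
        for rel, p in zip(outputs[stage], paths):
            if not p.exists():
                raise RuntimeError(f"stage {stage!r} did not produce {rel}")
            manifest.checksums[rel] = _sha256(p)
    manifest.to_json(out / "manifest.json")
    return manifest


def _render_report(config: RunConfig, out: Path) -> str:
    subjects = mio.read_subjects_csv(out / "subjects.csv")
    comps = pd.read_csv(out / "comparisons.csv", index_col="region_set")
    with open(out / "components.json") as fh:
        net = json.load(fh)
    lines = [
        "Covariance-network PET analysis report",
        "=" * 40,
        f"config hash: {config.config_hash()}",
        f"patients: {(subjects['group'] == 'patient').sum()}  "
        f"controls: {(subjects['group'] == 'control').sum()}",
        "",
        "Striatal group comparison (patient vs control):",
    ]
    s = comps.loc["striatum"]
    lines.append(
        f"  BP_ND {s['mean_patient']:.2f} +/- {s['sem_patient']:.2f} vs "
        f"{s['mean_control']:.2f} +/- {s['sem_control']:.2f}; "
        f"t = {s['t']:.2f}, df = {s['df']:.0f}, p = {s['p']:.3f}, "
        f"Cohen's d = {s['cohen_d']:.2f}"
    )
    lines.append("")
    lines.append(f"Covariance network ({net['n_edges_total']} edges):")
    for alpha in config.network_alphas:
        doc = net[str(alpha)]
        lines.append(f"  primary threshold alpha = {alpha}: "
                     f"{doc['n_significant_edges']} significant edges")
        sig = [c for c in doc["components"] if c["p_corrected"] < config.stats_alpha]
        if sig:
            for c in sig:
                lines.append(f"    component: {c['n_edges']} edges over "
                             f"{len(c['regions'])} regions, corrected p = {c['p_corrected']:.4g}")
        else:
            lines.append("    no significant components")
    return "\n".join(lines) + "\n"


def write_report(manifest_or_dir) -> str:
    """Render (and persist) the human-readable run summary; returns the text."""
    if isinstance(manifest_or_dir, RunManifest):
        raise TypeError("pass the run directory; the manifest does not store its location")
    out = Path(manifest_or_dir)
    with open(out / "provenance.json") as fh:
        raw = json.load(fh)["config"]
    cohort = CohortSpec(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw["cohort"].items()})
    config = RunConfig(
        seed=raw["seed"], output_dir=str(out), cohort=cohort,
        atlas_n_regions=raw["atlas_n_regions"], schedule_path=raw["schedule_path"],
        reference=raw["reference"], stats_variant=raw["stats_variant"],
        stats_alpha=raw["stats_alpha"],
        network_permutations=raw["network_permutations"],
        network_alphas=tuple(raw["network_alphas"]),
        network_direction=raw["network_direction"], network_seed=raw["network_seed"],
    )
    text = _render_report(config, out)
    (out / "report.txt").write_text(text)
    return text
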