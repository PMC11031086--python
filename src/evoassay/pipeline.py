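"""End-to-end pipeline: synthetic inputs -> stage analyses -> summary table.

A run is driven by a :class:`RunConfig` (TOML-serializable); every seed and
threshold used is recorded in a JSON manifest so a run can be reproduced
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assays import (
    EndocytosisRecord,
    build_summary_table,
    dose_response_auc,
    endocytosis_delta,
    read_dose_csv,
    sensitivity_at,
    write_dose_csv,
)
from .evolution import (
    CovariationCriteria,
    call_covariation,
    column_frequencies,
    conservation_scores,
    marginal_ancestral_reconstruction,
    mutual_information,
    poisson_aa_model,
    read_protein_fasta,
    write_protein_fasta,
)
from .flow import (
    SmoothingConfig,
    read_histogram_csv,
    response_stats,
    smooth,
    subtract_background,
    write_histogram_csv,
)
from .gradient import (
    auc_drm_dsm,
    cd4_percent_of_total,
    normalize_channel_to_cd4,
    read_gradient_csv,
    subtract_fraction1,
    write_gradient_csv,
)
from .synthetic import (
    EvoSimParams,
    FlowSimParams,
    GradientSimParams,
    balanced_tree_newick,
    gen_dose_series,
    gen_flow_pair,
    gen_gradient_profile,
    gen_protein_msa,
)

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]

ALL_STAGES = ("synthetic", "flow", "gradient", "dose", "evolve", "summary")
_STAGE_NEEDS = {
    "flow": ("synthetic",),
    "gradient": ("synthetic",),
    "dose": ("synthetic",),
    "evolve": ("synthetic",),
    "summary": ("flow", "gradient", "dose"),
}

SUMMARY_COLUMNS = (
    "IL-2 AUC",
    "IL-2 41 nM",
    "pCD3z MFI",
    "pCD3z response",
    "LCK DRM AUC",
    "LCK Total AUC",
    "LCK DSM AUC",
    "CD4 endocytosis",
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Declarative pipeline configuration with the printed defaults baked in."""

    seed: int = 1
    out_dir: str = "pipeline_out"
    stages: tuple[str, ...] = ALL_STAGES
    # flow
    smoothing_window: int = 500
    control_responder_fraction: float = 0.30
    mutant_responder_fraction: float = 0.18
    flow_shift: float = 1.2
    flow_events: int = 10_000
    # dose
    auc_axis: str = "log10"
    top_conc_uM: float = 30.0
    dilution: float = 3.0
    n_dose_points: int = 12
    mutant_top_scale: float = 0.6
    sensitivity_target_nM: float = 41.0
    # covariation thresholds
    mi_lo: float = 4.0
    cons_lo: float = -0.5
    mi_hi: float = 8.0
    cons_hi: float = -0.3
    select_fraction: float = 0.005
    # evolve stage sizing
    evolve_taxa: int = 12
    evolve_sites: int = 60
    evolve_branch_length: float = 0.15

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}")
        object.__setattr__(self, "stages", tuple(self.stages))
        enabled = set(self.stages)
        for stage in self.stages:
            missing = [d for d in _STAGE_NEEDS.get(stage, ()) if d not in enabled]
            if missing:
                raise ConfigError(
                    f"stage {stage!r} requires {missing} to be enabled"
                )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for key, value in self.to_dict().items():
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            elif isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            elif isinstance(value, (list, tuple)):
                items = ", ".join(f'"{v}"' for v in value)
                lines.append(f"{key} = [{items}]")
            else:
                lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    @property
    def criteria(self) -> CovariationCriteria:
        return CovariationCriteria(
            mi_lo=self.mi_lo,
            cons_lo=self.cons_lo,
            mi_hi=self.mi_hi,
            cons_hi=self.cons_hi,
            select_fraction=self.select_fraction,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "inputs": {},
        "outputs": [],
    }

    def register(path: Path, kind: str) -> None:
        rel = str(path.relative_to(out))
        if kind == "input":
            manifest["inputs"][rel] = _sha256(path)
        else:
            manifest["outputs"].append(rel)

    if "synthetic" in cfg.stages:
        _stage_synthetic(cfg, out, register)
    if "flow" in cfg.stages:
        _stage_flow(cfg, out, register)
    if "gradient" in cfg.stages:
        _stage_gradient(cfg, out, register)
    if "dose" in cfg.stages:
        _stage_dose(cfg, out, register)
    if "evolve" in cfg.stages:
        _stage_evolve(cfg, out, register)
    if "summary" in cfg.stages:
        _stage_summary(cfg, out, register)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# -- stages ----------------------------------------------------------------


def _line_params(cfg: RunConfig, line: str) -> FlowSimParams:
    frac = (
        cfg.control_responder_fraction
        if line == "control"
        else cfg.mutant_responder_fraction
    )
    return FlowSimParams(
        n_events=cfg.flow_events,
        responder_fraction=frac,
        shift=cfg.flow_shift,
        seed=cfg.seed + (0 if line == "control" else 1),
    )


def _stage_synthetic(cfg: RunConfig, out: Path, register) -> None:
    for line in ("control", "mutant"):
        null, agonist = gen_flow_pair(_line_params(cfg, line))
        write_histogram_csv(null, out / f"flow_{line}_null.csv")
        write_histogram_csv(agonist, out / f"flow_{line}_agonist.csv")
        register(out / f"flow_{line}_null.csv", "input")
        register(out / f"flow_{line}_agonist.csv", "input")

    amp = {
        "control": {"CD4": (60.0, 40.0), "LCK": (50.0, 20.0), "CTxB": (80.0, 10.0)},
        "mutant": {"CD4": (60.0, 40.0), "LCK": (15.0, 25.0), "CTxB": (80.0, 10.0)},
    }
    for line in ("control", "mutant"):
        profile = gen_gradient_profile(
            GradientSimParams(
                amplitudes=amp[line], noise_sd=1.0, seed=cfg.seed + (0 if line == "control" else 1)
            )
        )
        write_gradient_csv(profile, out / f"gradient_{line}.csv")
        register(out / f"gradient_{line}.csv", "input")

    for line, scale in (("control", 1.0), ("mutant", cfg.mutant_top_scale)):
        series = gen_dose_series(
            top_conc_uM=cfg.top_conc_uM,
            dilution=cfg.dilution,
            n_points=cfg.n_dose_points,
            fourpl=(0.0, 1000.0 * scale, 300.0, 1.0),
            cv=0.1,
            seed=cfg.seed + (0 if line == "control" else 1),
            line_id=line,
        )
        write_dose_csv(series, out / f"dose_{line}.csv")
        register(out / f"dose_{line}.csv", "input")

    classes = []
    for k in range(cfg.evolve_sites):
        if k % 5 == 0:
            classes.append("conserved")
        elif k in (1, 2):
            classes.append("covary:1")
        else:
            classes.append("neutral")
    msa = gen_protein_msa(
        EvoSimParams(
            tree=balanced_tree_newick(cfg.evolve_taxa, cfg.evolve_branch_length),
            site_classes=tuple(classes),
            seed=cfg.seed,
        )
    )
    write_protein_fasta(msa, out / "msa_protein.fasta")
    (out / "tree.nwk").write_text(msa.tree + "\n")
    register(out / "msa_protein.fasta", "input")
    register(out / "tree.nwk", "input")


def _stage_flow(cfg: RunConfig, out: Path, register) -> None:
    rows = []
    for line in ("control", "mutant"):
        agonist = read_histogram_csv(out / f"flow_{line}_agonist.csv", label="agonist")
        null = read_histogram_csv(out / f"flow_{line}_null.csv", label="null")
        diff = subtract_background(agonist, null)
        stats = response_stats(diff)
        rows.append(
            {
                "line": line,
                "percent_responders": stats.percent_responders,
                "mean_intensity": stats.mean_intensity,
                "sem_intensity": stats.sem_intensity,
                "positive_mass": stats.positive_mass,
            }
        )
        smoothed = smooth(diff, SmoothingConfig(window=cfg.smoothing_window))
        pd.DataFrame(
            {"bin_center": smoothed.bin_centers, "diff_smoothed": smoothed.diffs}
        ).to_csv(out / f"flow_{line}_smoothed.csv", index=False)
        register(out / f"flow_{line}_smoothed.csv", "output")
    pd.DataFrame(rows).to_csv(out / "flow_stats.csv", index=False)
    register(out / "flow_stats.csv", "output")


def _stage_gradient(cfg: RunConfig, out: Path, register) -> None:
    rows = []
    for line in ("control", "mutant"):
        profile = subtract_fraction1(read_gradient_csv(out / f"gradient_{line}.csv"))
        norm = normalize_channel_to_cd4(profile, "LCK")
        auc = auc_drm_dsm(norm)
        rows.append(
            {
                "line": line,
                "lck_drm_auc": auc.drm_auc,
                "lck_dsm_auc": auc.dsm_auc,
                "lck_total_auc": auc.total_auc,
            }
        )
        table = pd.DataFrame(
            {
                "cd4_percent": cd4_percent_of_total(profile),
                "lck_normalized": norm,
                "ctxb_normalized": normalize_channel_to_cd4(profile, "CTxB"),
            }
        )
        table.to_csv(out / f"gradient_{line}_normalized.csv")
        register(out / f"gradient_{line}_normalized.csv", "output")
    pd.DataFrame(rows).to_csv(out / "gradient_auc.csv", index=False)
    register(out / "gradient_auc.csv", "output")


def _stage_dose(cfg: RunConfig, out: Path, register) -> None:
    rows = []
    for line in ("control", "mutant"):
        series = read_dose_csv(out / f"dose_{line}.csv", line_id=line)
        rows.append(
            {
                "line": line,
                "il2_auc": dose_response_auc(series, axis=cfg.auc_axis),
                "il2_sensitivity": sensitivity_at(series, cfg.sensitivity_target_nM),
            }
        )
    pd.DataFrame(rows).to_csv(out / "dose_metrics.csv", index=False)
    register(out / "dose_metrics.csv", "output")


def _stage_evolve(cfg: RunConfig, out: Path, register) -> None:
    msa = read_protein_fasta(out / "msa_protein.fasta")
    msa = replace(msa, tree=(out / "tree.nwk").read_text().strip())
    cons = conservation_scores(msa)
    cons.to_csv(out / "site_conservation.tsv", sep="\t")
    register(out / "site_conservation.tsv", "output")
    column_frequencies(msa).to_csv(out / "logo_frequencies.csv")
    register(out / "logo_frequencies.csv", "output")
    pairs = mutual_information(msa)
    called = call_covariation(pairs, cons["conservation"], cfg.criteria)
    called.to_csv(out / "pair_covariation.tsv", sep="\t", index=False)
    register(out / "pair_covariation.tsv", "output")
    asr = marginal_ancestral_reconstruction(
        msa, list(msa.ids), model=poisson_aa_model()
    )
    (out / "mrca.fasta").write_text(f">mrca\n{asr.map_sequence}\n")
    asr.to_frame().to_csv(out / "mrca_posteriors.tsv", sep="\t", index_label="column")
    register(out / "mrca.fasta", "output")
    register(out / "mrca_posteriors.tsv", "output")


def _stage_summary(cfg: RunConfig, out: Path, register) -> None:
    flow = pd.read_csv(out / "flow_stats.csv").set_index("line")
    grad = pd.read_csv(out / "gradient_auc.csv").set_index("line")
    dose = pd.read_csv(out / "dose_metrics.csv").set_index("line")
    rng = np.random.default_rng([201, cfg.seed])
    metrics = {}
    for line in ("control", "mutant"):
        base = 100.0 if line == "control" else 90.0
        drop = 40.0 if line == "control" else 25.0
        endo = endocytosis_delta(
            EndocytosisRecord(
                gmfi_0uM=tuple(base + rng.normal(0, 2, 3)),
                gmfi_10uM=tuple(base - drop + rng.normal(0, 2, 3)),
            )
        )
        metrics[line] = {
            "IL-2 AUC": float(dose.loc[line, "il2_auc"]),
            "IL-2 41 nM": float(dose.loc[line, "il2_sensitivity"]),
            "pCD3z MFI": float(flow.loc[line, "mean_intensity"]),
            "pCD3z response": float(flow.loc[line, "percent_responders"]),
            "LCK DRM AUC": float(grad.loc[line, "lck_drm_auc"]),
            "LCK Total AUC": float(grad.loc[line, "lck_total_auc"]),
            "LCK DSM AUC": float(grad.loc[line, "lck_dsm_auc"]),
            "CD4 endocytosis": float(np.mean(endo)),
        }
    table = build_summary_table(
        metrics,
        {"control": "control", "mutant": "control"},
        columns=SUMMARY_COLUMNS,
    )
    table.to_csv(out / "summary_table.tsv", sep="\t", index_label="line")
    register(out / "summary_table.tsv", "output")
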