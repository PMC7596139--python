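"""End-to-end pipeline: simulate, derive, score, bootstrap, connectome, report.

``run_pipeline`` chains the analysis stages on disk: every stage writes its
artifact files plus one shared run manifest recording seeds, parameters and
output checksums, so a rerun with an identical configuration reproduces
identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import rm_anova, summarize, two_sample_t
from .cohort import CohortMatrix
from .connectome import sparsity_sweep
from .expression import apply_cohort_offset, score_cohort, z_reference
from .inference import permutation_metric_test
from .io import (
    read_cohort_table,
    read_pattern,
    write_cohort_table,
    write_pattern,
    write_truth,
)
from .reliability import bootstrap_pattern
from .simulate import SimulationConfig, simulate_cohort, simulate_longitudinal
from .ssm import derive_pattern, partition_subspace, preprocess_profiles

__all__ = ["run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = (
    "simulate",
    "derive",
    "score",
    "bootstrap",
    "connectome",
    "permtest",
    "report",
)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    def __init__(self, outdir: Path, seed: int, config: dict):
        self.path = outdir / "manifest.json"
        self.entries: list[dict] = []
        self.header = {
            "version": __version__,
            "seed": seed,
            "config": config,
        }

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.entries.append(
            {
                "stage": stage,
                "params": params,
                "outputs": {p.name: _checksum(p) for p in outputs},
            }
        )
        self.path.write_text(
            json.dumps({**self.header, "stages": self.entries}, indent=1)
        )


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} requires {path.name}, produced by the "
            f"{produced_by!r} stage; run it first"
        )
    return path


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    config: SimulationConfig | None = None,
    sparsity: float = 0.25,
    n_perm: int = 200,
    n_boot: int = 100,
) -> dict[str, list[str]]:
    """Run the requested stages, writing artifacts and a manifest to outdir.

    Returns a mapping of stage name to the files it wrote.  Stages consume
    the artifacts of earlier stages from ``outdir`` and fail with an
    explicit dependency error if a required upstream file is missing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SimulationConfig(seed=seed)
    if config.seed != seed:
        config = config.with_seed(seed)
    manifest = _Manifest(outdir, seed, asdict(config))
    written: dict[str, list[str]] = {}

    derivation_path = outdir / "cohort_derivation.tsv"
    followup_path = outdir / "cohort_followup.tsv"
    pattern_path = outdir / "pattern.json"
    scores_path = outdir / "scores.tsv"

    for stage in stages:
        if stage == "simulate":
            cohort, truth = simulate_cohort(config)
            follow, truth2 = simulate_longitudinal(
                SimulationConfig.dbs_cohort(seed=seed)
            )
            write_cohort_table(cohort, derivation_path)
            write_cohort_table(follow, followup_path)
            write_truth(truth, outdir / "truth_derivation.json")
            write_truth(truth2, outdir / "truth_followup.json")
            outs = [
                derivation_path,
                followup_path,
                outdir / "truth_derivation.json",
                outdir / "truth_followup.json",
            ]
        elif stage == "derive":
            cohort = read_cohort_table(
                _require(derivation_path, stage, "simulate")
            )
            pattern = derive_pattern(preprocess_profiles(cohort))
            write_pattern(pattern, pattern_path)
            outs = [pattern_path]
        elif stage == "score":
            pattern = read_pattern(_require(pattern_path, stage, "derive"))
            cohort = read_cohort_table(
                _require(derivation_path, stage, "simulate")
            )
            follow = read_cohort_table(
                _require(followup_path, stage, "simulate")
            )
            raw_der = score_cohort(cohort, pattern)
            hc_ref = raw_der[cohort.group_mask("HC")]
            raw_fol = score_cohort(follow, pattern)
            scores = z_reference(
                raw_fol,
                hc_ref,
                subject_ids=follow.subject_ids,
                group_labels=follow.group_labels,
                timepoint_labels=follow.timepoint_labels,
            )
            scores = apply_cohort_offset(
                scores, scores.z_score[follow.group_mask("HC")]
            )
            pd.DataFrame(
                {
                    "subject_id": scores.subject_ids,
                    "group": scores.group_labels,
                    "timepoint": scores.timepoint_labels,
                    "raw_tpr": scores.raw_tpr,
                    "z_score": scores.z_score,
                    "z_corrected": scores.z_corrected,
                }
            ).to_csv(scores_path, sep="\t", index=False)
            outs = [scores_path]
        elif stage == "bootstrap":
            cohort = read_cohort_table(
                _require(derivation_path, stage, "simulate")
            )
            rel = bootstrap_pattern(cohort, n_boot=n_boot, seed=seed)
            out = outdir / "reliability.tsv"
            pd.DataFrame(
                {
                    "roi_id": rel.roi_ids,
                    "point_weight": rel.point_weights,
                    "boot_z": rel.boot_z,
                    "reliable": rel.mask,
                }
            ).to_csv(out, sep="\t", index=False)
            outs = [out]
        elif stage == "connectome":
            pattern = read_pattern(_require(pattern_path, stage, "derive"))
            follow = read_cohort_table(
                _require(followup_path, stage, "simulate")
            )
            part = partition_subspace(pattern.z_weights, pattern.roi_ids)
            rows = []
            for group in ("HC", "PD"):
                sub = follow.subset_group(group)
                if group == "PD":
                    base = np.asarray(sub.timepoint_labels) == "baseline"
                    sub = sub.select(base)
                for label, nodes in (
                    ("disease", part.disease_rois),
                    ("non_subspace", part.non_subspace_rois),
                ):
                    for gm in sparsity_sweep(
                        sub, nodes, grid=(sparsity,), seed=seed
                    ):
                        rows.append(
                            {
                                "group": group,
                                "node_set": label,
                                "sparsity": gm.sparsity,
                                "C": gm.C,
                                "L": gm.L,
                                "S": gm.S,
                                "C_rand": gm.C_rand,
                                "L_rand": gm.L_rand,
                                "connected": gm.connected,
                            }
                        )
            out = outdir / "metrics.tsv"
            pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
            outs = [out]
        elif stage == "permtest":
            pattern = read_pattern(_require(pattern_path, stage, "derive"))
            follow = read_cohort_table(
                _require(followup_path, stage, "simulate")
            )
            part = partition_subspace(pattern.z_weights, pattern.roi_ids)
            hc = follow.subset_group("HC")
            pdg = follow.subset_group("PD")
            base = np.asarray(pdg.timepoint_labels) == "baseline"
            pdg = pdg.select(base)
            rows = []
            for metric in ("C", "L", "S"):
                res = permutation_metric_test(
                    pdg,
                    hc,
                    part.disease_rois,
                    sparsity,
                    metric=metric,
                    n_perm=n_perm,
                    seed=seed,
                )
                rows.append(
                    {
                        "metric": metric,
                        "node_set": "disease",
                        "sparsity": sparsity,
                        "observed": res.observed,
                        "p_value": res.p_value,
                        "n_perm": res.n_perm,
                        "seed": seed,
                    }
                )
            out = outdir / "permtests.tsv"
            pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
            outs = [out]
        elif stage == "report":
            scores = pd.read_csv(
                _require(scores_path, stage, "score"), sep="\t"
            )
            lines = []
            hc_z = scores.loc[scores["group"] == "HC", "z_corrected"]
            lines.append(
                "corrected control z: mean %.3f sd %.3f"
                % summarize(hc_z.to_numpy())
            )
            pd_scores = scores[scores["group"] == "PD"]
            wide = pd_scores.pivot_table(
                index="subject_id", columns="timepoint", values="z_corrected"
            )
            cols = [c for c in ("baseline", "3mo", "12mo") if c in wide]
            wide = wide[cols]
            for c in cols:
                mu, sd = summarize(wide[c].to_numpy())
                lines.append(f"patient z at {c}: {mu:.3f} +/- {sd:.3f}")
            base = scores[
                (scores["group"] == "PD") & (scores["timepoint"] == "baseline")
            ]["z_corrected"]
            tt = two_sample_t(base.to_numpy(), hc_z.to_numpy())
            lines.append(
                f"baseline patients vs controls: t={tt.statistic:.3f} "
                f"p={tt.p_value:.4f}"
            )
            if len(cols) == 3:
                res = rm_anova(wide.to_numpy())
                lines.append(
                    "rm-ANOVA on complete patients: F(%d,%d)=%.3f p=%.4f"
                    % (int(res.df[0]), int(res.df[1]), res.statistic, res.p_value)
                )
            out = outdir / "report.txt"
            out.write_text("\n".join(lines) + "\n")
            outs = [out]
        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest.record(stage, {"seed": seed}, outs)
        written[stage] = [p.name for p in outs]
    return written
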