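"""End-to-end study pipeline.

``run_study`` reproduces the study workflow on an emulated data set: invert
the double-column model per segment (shared-noise PSO), compute PDC flows
per segment, average both across the segments of each subject x condition
cell, and run the repeated-measures group statistics on every measure.

The pipeline is restartable: per-segment inversion results and flow
summaries are cached as JSON under the output directory and reused on rerun.
Every results file embeds the configuration hash and global seed; rerunning
with the same configuration and seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .group_stats import ConditionTable, posthoc_paired_bonferroni, rm_anova_gg
from .inversion import InversionResult, PSOConfig, average_segment_results, invert_segment
from .io import read_segment
from .neural_mass import DoubleColumnParams, PARAM_NAMES
from .pdc import FlowSummary, segment_flows
from .synthetic_data import (
    DEFAULT_GROUPS,
    StimulusSpec,
    StudyFixture,
    generate_study_fixture,
    load_manifest,
    make_stimulus_input,
)

__all__ = ["StudyConfig", "StudyResult", "DesignCompletenessError", "run_study"]

FLOW_MEASURES = ("vc_to_fa", "fa_to_vc", "within_vc", "within_fa")


class DesignCompletenessError(ValueError):
    """A subject is missing a condition or a segment of the study design."""


@dataclass(frozen=True)
class StudyConfig:
    """Everything `run_study` needs; fully determines the results bundle
    together with nothing else (all randomness is seeded from ``seed``)."""

    fixture: StudyFixture | None = None
    study_dir: str | None = None
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    pso: PSOConfig = field(default_factory=PSOConfig)
    band: tuple = (6.0, 92.0)
    order_range: tuple = (5, 20)
    reference_condition: str = "8"
    seed: int = 0
    stages: tuple = ("inversion", "pdc", "stats")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.fixture is not None:
            d["fixture"]["true_params"] = {
                c: {k: getattr(p, k) for k in PARAM_NAMES}
                for c, p in self.fixture.true_params.items()
            }
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyResult:
    params: pd.DataFrame  # subject x condition rows with C1, C2, K1, K2
    flows: pd.DataFrame  # subject x condition rows with the four flow sums
    stats: dict  # measure -> {"anova": ..., "posthoc": [...]}
    config_digest: str
    out_dir: Path

    def condition_means(self, table: str = "params") -> pd.DataFrame:
        df = self.params if table == "params" else self.flows
        return df.groupby("condition", sort=False).mean(numeric_only=True)


def _segment_seed(global_seed: int, *indices) -> int:
    ss = np.random.SeedSequence([int(global_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


def _check_design(manifest: dict) -> None:
    conditions = manifest["conditions"]
    n_seg = manifest["segments_per_condition"]
    for sub in manifest["subjects"]:
        missing = [c for c in conditions if c not in sub["conditions"]]
        if missing:
            raise DesignCompletenessError(
                f"subject {sub['id']} lacks conditions {missing}"
            )
        for c in conditions:
            got = len(sub["conditions"][c]["segments"])
            if got != n_seg:
                raise DesignCompletenessError(
                    f"subject {sub['id']} condition {c}: {got} segments, expected {n_seg}"
                )


def _drives_for(manifest: dict, condition: str, model_seed: int):
    spec = StimulusSpec(
        condition=condition,
        pulse_amplitude=manifest["pulse_amplitude"],
        duration=manifest["duration"] + manifest["burn_in"],
        fs=manifest["fs"],
    )
    s_p, s_pp = np.random.SeedSequence(model_seed).spawn(2)
    p = make_stimulus_input(spec, s_p)
    pp = make_stimulus_input(dataclasses.replace(spec, condition="control"), s_pp)
    return p, pp


def _cached(path: Path, compute, encode, decode):
    if path.exists():
        with open(path) as fh:
            return decode(json.load(fh))
    value = compute()
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(encode(value), fh, sort_keys=True)
    return value


def run_study(config: StudyConfig, out_dir) -> StudyResult:
    """Run the configured stages and write the results bundle to ``out_dir``.

    Bundle layout: ``fixture/`` (generated when a fixture spec is given),
    ``inversion/`` and ``flows/`` per-segment caches, ``tables/params.csv``
    and ``tables/flows.csv`` (per subject x condition averages over
    segments), ``stats.json`` and ``summary.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()

    if config.study_dir is not None:
        study_dir = Path(config.study_dir)
    elif config.fixture is not None:
        study_dir = out_dir / "fixture"
        if not (study_dir / "manifest.json").exists():
            generate_study_fixture(config.fixture, study_dir, overwrite=True)
    else:
        raise ValueError("StudyConfig needs either a fixture spec or a study_dir")
    manifest = load_manifest(study_dir)
    _check_design(manifest)
    conditions = manifest["conditions"]

    param_rows, flow_rows = [], []
    for si, sub in enumerate(manifest["subjects"]):
        for ci, cond in enumerate(conditions):
            cell = sub["conditions"][cond]
            seg_results, seg_flows = [], []
            for seg in cell["segments"]:
                tag = f"{sub['id']}_{cond}_seg{seg['index']}"
                if "inversion" in config.stages:
                    def invert_one(seg=seg, cond=cond, si=si, ci=ci):
                        segment = read_segment(study_dir / seg["model_path"])
                        drives = _drives_for(manifest, cond, seg["model_seed"])
                        return invert_segment(
                            segment,
                            cond,
                            drives,
                            config=config.pso,
                            seed=_segment_seed(config.seed, si, ci, seg["index"]),
                            burn_in=manifest["burn_in"],
                        )
                    result = _cached(
                        out_dir / "inversion" / f"{tag}.json",
                        invert_one,
                        lambda r: r.as_dict(),
                        _decode_inversion,
                    )
                    seg_results.append(result)
                if "pdc" in config.stages:
                    def flows_one(seg=seg):
                        segment = read_segment(study_dir / seg["lfp_path"])
                        summary, _, order = segment_flows(
                            segment, config.groups, config.band, config.order_range
                        )
                        return summary, order
                    summary, order = _cached(
                        out_dir / "flows" / f"{tag}.json",
                        flows_one,
                        lambda v: {**v[0].as_dict(), "order": v[1]},
                        lambda d: (
                            FlowSummary(**{k: d[k] for k in FLOW_MEASURES}),
                            d["order"],
                        ),
                    )
                    seg_flows.append(summary)
            if seg_results:
                mean_params = average_segment_results(seg_results)
                param_rows.append(
                    {
                        "subject": sub["id"],
                        "condition": cond,
                        **{k: getattr(mean_params, k) for k in PARAM_NAMES},
                    }
                )
            if seg_flows:
                flow_rows.append(
                    {
                        "subject": sub["id"],
                        "condition": cond,
                        **{
                            m: float(np.mean([getattr(f, m) for f in seg_flows]))
                            for m in FLOW_MEASURES
                        },
                    }
                )

    params_df = pd.DataFrame(param_rows)
    flows_df = pd.DataFrame(flow_rows)
    tables_dir = out_dir / "tables"
    tables_dir.mkdir(exist_ok=True)
    if not params_df.empty:
        params_df.to_csv(tables_dir / "params.csv", index=False)
    if not flows_df.empty:
        flows_df.to_csv(tables_dir / "flows.csv", index=False)

    stats: dict = {}
    if "stats" in config.stages:
        measures = []
        if not params_df.empty:
            measures += [(params_df, m) for m in PARAM_NAMES]
        if not flows_df.empty:
            measures += [(flows_df, m) for m in FLOW_MEASURES]
        for df, measure in measures:
            wide = df.pivot(index="subject", columns="condition", values=measure)
            wide = wide.reindex(columns=conditions)
            table = ConditionTable.from_dataframe(wide)
            anova = rm_anova_gg(table)
            posthoc = posthoc_paired_bonferroni(table, config.reference_condition)
            stats[measure] = {
                "anova": anova.as_dict(),
                "posthoc": [c.as_dict() for c in posthoc],
            }
        with open(out_dir / "stats.json", "w") as fh:
            json.dump({"seed": config.seed, "config": digest, "measures": stats},
                      fh, indent=1, sort_keys=True)

    summary = {
        "seed": config.seed,
        "config": digest,
        "stages": list(config.stages),
        "n_subjects": len(manifest["subjects"]),
        "conditions": conditions,
        "segments_per_condition": manifest["segments_per_condition"],
        "condition_means": {},
    }
    for name, df in (("params", params_df), ("flows", flows_df)):
        if not df.empty:
            means = df.groupby("condition", sort=False).mean(numeric_only=True)
            summary["condition_means"][name] = {
                c: {k: float(v) for k, v in row.items()}
                for c, row in means.round(12).iterrows()
            }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    return StudyResult(params_df, flows_df, stats, digest, out_dir)


def _decode_inversion(d: dict) -> InversionResult:
    return InversionResult(
        params=DoubleColumnParams(**d["params"]),
        fitness=d["fitness"],
        trace=np.asarray(d["trace"]),
        generations=d["generations"],
        seed=d["seed"],
        relative_errors=d["relative_errors"],
        condition=d["condition"],
    )
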