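"""End-to-end orchestration of a multi-group, multi-donor experiment.

A declarative config names the protocol preset, the groups (each with its
own simulation parameters, or trace CSV paths in ingest mode), the donors,
the contrasts to test, and the analysis parameters.  ``run_experiment``
simulates or loads every group × donor recording, runs the trace analysis,
and produces:

* a per-ROI metrics table (group, donor, MFES, peak frequency, peak
  height, responder class, evoked metrics) with the thresholds used,
* technical-level statistics per contrast (rank-sum per metric, chi-square
  on responder proportions),
* donor-level paired t-tests on per-donor medians,
* a machine-readable JSON summary.

Determinism: the single top-level seed is expanded into one independent
child seed per (group, donor) stage through ``numpy``'s ``SeedSequence``
spawning, in the fixed order groups-then-donors, so any stage can be rerun
in isolation and a rerun of the whole pipeline is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gliakit import synthetic
from gliakit.protocols import PROTOCOLS
from gliakit.stats import (
    GroupSample,
    TestResult,
    donor_level_paired_test,
    pairwise_rank_sum,
    proportion_chi_square,
    results_frame,
)
from gliakit.traces import (
    classify_evoked_responders,
    detect_spontaneous_peaks,
    detect_spontaneous_peaks_pooled,
    evoked_response_metrics,
    normalize_dff,
    roi_spontaneous_metrics,
)

logger = logging.getLogger(__name__)

TRACE_METRICS = ("mfes", "peak_frequency", "peak_height")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    protocol: str = "drg_rat"
    groups: dict[str, dict] = field(default_factory=dict)   # label -> TraceSimConfig overrides
    n_donors: int = 3
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    percentile: float = 95.0
    responder_rule: str = "spontaneous_percentile"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        for a, b in self.contrasts:
            for label in (a, b):
                if label not in self.groups:
                    raise ValueError(f"contrast references unknown group {label!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        raw["contrasts"] = [tuple(c) for c in raw.get("contrasts", [])]
        return cls(**raw)


@dataclass
class ExperimentReport:
    roi_metrics: pd.DataFrame
    technical_tests: list[TestResult]
    donor_tests: list[TestResult]
    proportion_tests: list[TestResult]
    config: ExperimentConfig

    def summary(self) -> dict:
        def pack(results):
            return [
                {
                    "contrast": r.contrast,
                    "test": r.test_name,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "significant": r.significant,
                    "n": list(r.n),
                    "details": {k: v for k, v in r.details.items()
                                if isinstance(v, (int, float, str, bool, list, tuple))},
                }
                for r in results
            ]

        return {
            "protocol": self.config.protocol,
            "seed": self.config.seed,
            "groups": sorted(self.config.groups),
            "n_rois_analyzed": int(len(self.roi_metrics)),
            "technical_tests": pack(self.technical_tests),
            "donor_tests": pack(self.donor_tests),
            "proportion_tests": pack(self.proportion_tests),
        }


def _sim_config_for(config: ExperimentConfig, label: str, child_seed: int) -> synthetic.TraceSimConfig:
    proto = PROTOCOLS[config.protocol]
    overrides = dict(config.groups[label])
    overrides.pop("seed", None)
    base = dict(
        duration_s=proto.total_duration_s,
        stimulus_time_s=proto.stimuli[0].time_s if proto.stimuli else None,
    )
    base.update(overrides)
    return synthetic.TraceSimConfig(seed=child_seed, **base)


def analyze_normalized(norm, detection, responder_rule: str = "spontaneous_percentile",
                       percentile: float = 95.0) -> pd.DataFrame:
    """Turn one normalized recording plus its detection into a tidy table.

    Non-responder ROIs keep their spontaneous metrics but carry NaN evoked
    metrics, mirroring the exclusion of dead/non-neuronal ROIs.
    """
    spont = roi_spontaneous_metrics(detection, norm)
    classification = classify_evoked_responders(
        norm, rule=responder_rule, rule_percentile=percentile, spontaneous_events=detection
    )
    evoked = {m.roi_id: m for m in evoked_response_metrics(norm, classification)}
    rows = []
    for m in spont:
        ev = evoked.get(m.roi_id)
        rows.append(
            {
                "roi_id": m.roi_id,
                "mfes": m.mfes,
                "peak_frequency": m.peak_frequency,
                "peak_height": m.peak_height,
                "has_spontaneous_response": m.has_spontaneous_response,
                "roi_class": classification.classes[m.roi_id],
                "is_responder": m.roi_id in set(classification.responder_ids.tolist()),
                "evoked_peak_height": ev.evoked_peak_height if ev else float("nan"),
                "flux_duration_s": ev.flux_duration_s if ev else float("nan"),
                "detection_threshold": detection.threshold,
                "detection_percentile": detection.percentile,
                "responder_threshold": classification.threshold,
                "responder_rule": classification.rule,
            }
        )
    return pd.DataFrame(rows)


def analyze_trace_set(traces, percentile: float = 95.0,
                      responder_rule: str = "spontaneous_percentile") -> pd.DataFrame:
    """Full single-recording analysis (per-recording detection threshold)."""
    norm = normalize_dff(traces)
    detection = detect_spontaneous_peaks(norm, percentile=percentile)
    return analyze_normalized(norm, detection, responder_rule, percentile)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Simulate and analyze every group × donor, then run both statistics levels.

    All recordings of the experiment share one detection threshold (pooled
    candidate percentile) so event counts are comparable across groups; see
    :func:`gliakit.traces.detect_spontaneous_peaks_pooled`.
    """
    if not config.groups:
        raise ValueError("config defines no groups")
    t_start = time.perf_counter()
    labels = sorted(config.groups)
    children = np.random.SeedSequence(config.seed).spawn(len(labels) * config.n_donors)
    stages, norms = [], []
    for gi, label in enumerate(labels):
        for donor in range(config.n_donors):
            child = children[gi * config.n_donors + donor]
            child_seed = int(child.generate_state(1)[0] % (2**31))
            sim = _sim_config_for(config, label, child_seed)
            stage = f"{label}/donor{donor}"
            try:
                traces, _ = synthetic.simulate_trace_set(sim)
                norms.append(normalize_dff(traces))
            except Exception as exc:  # annotate which stage broke
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            stages.append((label, donor))
    detections = detect_spontaneous_peaks_pooled(norms, percentile=config.percentile)
    tables = []
    for (label, donor), norm, detection in zip(stages, norms, detections):
        stage = f"{label}/donor{donor}"
        try:
            table = analyze_normalized(norm, detection, config.responder_rule, config.percentile)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        table.insert(0, "group", label)
        table.insert(1, "donor", f"donor{donor}")
        tables.append(table)
        logger.info("stage %s done (%.2fs elapsed)", stage, time.perf_counter() - t_start)
    roi_metrics = pd.concat(tables, ignore_index=True)

    technical, donor_level, proportions = [], [], []
    for metric in TRACE_METRICS:
        sub = roi_metrics.dropna(subset=[metric])
        groups = {
            label: GroupSample(
                label,
                sub.loc[sub.group == label, metric].to_numpy(),
                sub.loc[sub.group == label, "donor"].to_numpy(),
            )
            for label in labels
            if (sub.group == label).any()
        }
        for a, b in config.contrasts:
            if a in groups and b in groups:
                res = pairwise_rank_sum(groups, [(a, b)])[0]
                res.details["metric"] = metric
                technical.append(res)
                dres = donor_level_paired_test(groups[a], groups[b])
                dres.details["metric"] = metric
                donor_level.append(dres)
    for a, b in config.contrasts:
        ka = int(roi_metrics.loc[roi_metrics.group == a, "is_responder"].sum())
        na = int((roi_metrics.group == a).sum())
        kb = int(roi_metrics.loc[roi_metrics.group == b, "is_responder"].sum())
        nb = int((roi_metrics.group == b).sum())
        res = proportion_chi_square(ka, na, kb, nb)
        res.contrast = f"{a} vs {b}"
        res.details["metric"] = "responder_proportion"
        proportions.append(res)

    report = ExperimentReport(roi_metrics, technical, donor_level, proportions, config)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        roi_metrics.to_csv(out / "roi_metrics.csv", index=False)
        results_frame(technical + proportions).to_csv(out / "technical_tests.csv", index=False)
        if donor_level:
            results_frame(donor_level).to_csv(out / "donor_tests.csv", index=False)
        (out / "summary.json").write_text(json.dumps(report.summary(), indent=2))
        cfg = dataclasses.asdict(config)
        cfg["contrasts"] = [list(c) for c in cfg["contrasts"]]
        (out / "config.json").write_text(json.dumps(cfg, indent=2))
    return report
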