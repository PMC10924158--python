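"""End-to-end experiment orchestration.

A single YAML config describes a study: the synthetic cohort (size,
population distributions, scanner presets), the algorithms to run
(SUVmax fractions, Snakes, MRF-GMM, U-net variants), and the evaluation
plan (algorithm pairs for paired testing and per-case concordance).
``run_experiment`` executes the stages in order — simulate, segment,
quantify, evaluate, concordance — and writes an EvaluationTable CSV,
per-pair summary JSON, delta scatter CSV/PNG, and a manifest. A rerun
with the same config and seed is byte-identical on all CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from petseval import __version__
from petseval.concordance import (
    compute_deltas,
    discordance_summary,
    plot_scatter,
    scatter_table,
    AGNOSTIC_FOMS,
    TASK_FOMS,
)
from petseval.conventional import (
    MRFGMMParams,
    SnakesParams,
    roi_from_mask,
    segment_mrf_gmm,
    segment_snakes,
    segment_suvmax_threshold,
)
from petseval.foms import evaluate_case, summarize_and_test
from petseval.phantom import (
    PhantomRecord,
    PopulationConfig,
    ScannerConfig,
    generate_cohort,
)


@dataclass
class ExperimentConfig:
    n: int
    seed: int
    population: PopulationConfig
    scanners: list[ScannerConfig]
    suvmax_fractions: list[float] = field(default_factory=lambda: [0.4, 0.5])
    snakes: dict | None = None
    mrf_gmm: dict | None = None
    unet: dict | None = None
    pairs: list[tuple[str, str]] = field(default_factory=list)
    roi_margin: int = 8
    raw: dict = field(default_factory=dict)

    @property
    def algorithm_ids(self) -> list[str]:
        ids = [f"suvmax{int(round(f * 100))}" for f in self.suvmax_fractions]
        if self.snakes is not None:
            ids.append("snakes")
        if self.mrf_gmm is not None:
            ids.append("mrf_gmm")
        if self.unet is not None:
            for d in self.unet.get("depths", []):
                ids.append(f"unet_d{d}")
            for lam in self.unet.get("lambdas", []):
                ids.append(f"unet_lam{lam:g}")
        return ids

    def validate(self) -> None:
        known = set(self.algorithm_ids)
        for a, b in self.pairs:
            for alg in (a, b):
                if alg not in known:
                    raise ValueError(
                        f"evaluation pair references unknown algorithm {alg!r}; "
                        f"registered: {sorted(known)}"
                    )

    @classmethod
    def from_dict(cls, d: dict, seed: int | None = None) -> "ExperimentConfig":
        cohort = d["cohort"]
        algos = d.get("algorithms", {})
        ev = d.get("evaluation", {})
        cfg = cls(
            n=int(cohort["n"]),
            seed=int(seed if seed is not None else cohort.get("seed", 0)),
            population=PopulationConfig(**cohort.get("population", {})),
            scanners=[ScannerConfig(**s) for s in cohort["scanners"]],
            suvmax_fractions=list(algos.get("suvmax_fractions", [0.4, 0.5])),
            snakes=algos.get("snakes"),
            mrf_gmm=algos.get("mrf_gmm"),
            unet=algos.get("unet"),
            pairs=[tuple(p) for p in ev.get("pairs", [])],
            roi_margin=int(ev.get("roi_margin", 8)),
            raw=d,
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), seed=seed)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Fan the global seed out to per-stage child seeds (documented derivation)."""
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n)]


def segment_record(
    record: PhantomRecord, config: ExperimentConfig
) -> dict[str, Any]:
    """Run every configured conventional algorithm on one case."""
    roi = roi_from_mask(record.truth_mask, margin=config.roi_margin)
    roi = _clip_roi(roi, record.volume.shape)
    masks = {}
    for f in config.suvmax_fractions:
        masks[f"suvmax{int(round(f * 100))}"] = segment_suvmax_threshold(
            record.volume, roi, f
        )
    if config.snakes is not None:
        masks["snakes"] = segment_snakes(
            record.volume, roi, SnakesParams(**config.snakes)
        )
    if config.mrf_gmm is not None:
        masks["mrf_gmm"] = segment_mrf_gmm(
            record.volume, roi, MRFGMMParams(**config.mrf_gmm)
        )
    return masks


def _clip_roi(roi, shape):
    from petseval.core import AnalysisROI

    stop = tuple(min(b, s) for b, s in zip(roi.stop, shape))
    return AnalysisROI(roi.start, stop)


def _run_unet_block(
    records: list[PhantomRecord], config: ExperimentConfig, unet_seed: int
) -> tuple[list[dict], dict]:
    """Train configured U-net variants and evaluate them on held-out cases."""
    from petseval.unet import UNetConfig, predict_volume, train_unet

    u = config.unet
    test_fraction = float(u.get("test_fraction", 0.3))
    rng = np.random.default_rng(unet_seed)
    order = rng.permutation(len(records))
    n_test = max(1, int(round(test_fraction * len(records))))
    test_idx = sorted(int(i) for i in order[:n_test])
    train_recs = [r for i, r in enumerate(records) if i not in set(test_idx)]
    test_recs = [records[i] for i in test_idx]
    base = {
        "base_filters": int(u.get("base_filters", 8)),
        "dropout_p": float(u.get("dropout_p", 0.1)),
        "lr": float(u.get("lr", 3e-3)),
        "epochs": int(u.get("epochs", 20)),
        "batch_size": int(u.get("batch_size", 4)),
        "folds": int(u.get("folds", 2)),
        "seed": unet_seed,
    }
    variants: dict[str, UNetConfig] = {}
    for d in u.get("depths", []):
        variants[f"unet_d{d}"] = UNetConfig(depth=int(d), loss="bce", **base)
    lam_depth = int(u.get("lambda_depth", 3))
    for lam in u.get("lambdas", []):
        variants[f"unet_lam{lam:g}"] = UNetConfig(
            depth=lam_depth, loss="combined", lam=float(lam), **base
        )
    rows, reports = [], {}
    for name, ucfg in variants.items():
        model, report = train_unet(train_recs, ucfg)
        reports[name] = report.to_dict()
        for rec in test_recs:
            _, pred = predict_volume(model, rec.volume)
            rows.append(
                evaluate_case(
                    rec.truth_mask,
                    pred,
                    rec.volume,
                    rec.true_mtv,
                    rec.true_tlg,
                    rec.case_id,
                    name,
                )
            )
    return rows, {"cv_reports": reports, "test_cases": [records[i].case_id for i in test_idx]}


def run_experiment(config: ExperimentConfig, outdir) -> dict[str, Any]:
    """Execute the full pipeline and write the report bundle to ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # the cohort is the root stage and consumes the global seed directly
    # (it spawns per-case child seeds itself); later stages that need
    # their own randomness get spawned children
    cohort_seed = config.seed
    (unet_seed,) = _child_seeds(config.seed, 1)

    stage = "simulate"
    try:
        records = generate_cohort(
            config.n, config.population, config.scanners, cohort_seed
        )
        rows: list[dict] = []
        for rec in records:
            stage = f"segment/{rec.case_id}"
            masks = segment_record(rec, config)
            stage = f"evaluate/{rec.case_id}"
            for alg, mask in masks.items():
                rows.append(
                    evaluate_case(
                        rec.truth_mask,
                        mask,
                        rec.volume,
                        rec.true_mtv,
                        rec.true_tlg,
                        rec.case_id,
                        alg,
                    )
                )
        unet_info = None
        if config.unet is not None:
            stage = "unet"
            unet_rows, unet_info = _run_unet_block(records, config, unet_seed)
            rows.extend(unet_rows)
    except Exception as err:
        raise RuntimeError(f"experiment failed at stage {stage}: {err}") from err

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "evaluation_table.csv", index=False)

    summaries = {}
    discordance: dict[str, Any] = {}
    for a, b in config.pairs:
        key = f"{a}_vs_{b}"
        summary = summarize_and_test(table, (a, b))
        summaries[key] = summary.to_dict()
        deltas = compute_deltas(table, a, b)
        deltas.to_csv(outdir / f"deltas_{key}.csv", index=False)
        discordance[key] = {}
        for ag in AGNOSTIC_FOMS:
            for tk in TASK_FOMS:
                ds = discordance_summary(deltas, ag, tk)
                discordance[key][f"{ag}__{tk}"] = ds.to_dict()
                scatter_table(deltas, ag, tk).to_csv(
                    outdir / f"scatter_{key}_{ag}_{tk}.csv", index=False
                )
        plot_scatter(deltas, "dsc", "mtv_ane", outdir / f"scatter_{key}_dsc_mtv.png")

    (outdir / "summaries.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True)
    )
    (outdir / "discordance.json").write_text(
        json.dumps(discordance, indent=2, sort_keys=True)
    )
    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(config.raw, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stage_seeds": {"cohort": cohort_seed, "unet": unet_seed},
        "n_cases": config.n,
        "algorithms": config.algorithm_ids,
        "petseval_version": __version__,
    }
    if config.unet is not None and unet_info is not None:
        manifest["unet"] = unet_info
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "table": table,
        "summaries": summaries,
        "discordance": discordance,
        "manifest": manifest,
    }
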