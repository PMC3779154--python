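"""End-to-end screen analysis: correction, normalization, fitting, hit calling.

Every stage writes a plain-text artifact into the output directory:

* ``raw/<sample>.csv`` and ``truth.csv`` (simulated screens only),
* ``qc.csv`` — per-plate Z'-factor, S/B ratio and DMSO CV,
* ``normalized.csv`` — long-format corrected + normalized well table,
* ``fits.csv`` — 4PL parameters, curve class and category per
  compound x sample,
* ``consensus_hits.csv``, ``selectivity.csv`` — hit calling,
* ``summary.json`` — screen summary plus provenance (package version,
  config hash, seed),
* ``heatmap.tsv`` and ``dendrogram.nwk`` — clustered activity profiles.

Given a fixed config and seed the artifacts are bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, plates
from .classify import CurveClassifier
from .config import ScreenConfig
from .doseresponse import fit_table
from .errors import QhtsError
from .hits import (
    activity_matrix_from_fits,
    call_selectivity,
    cluster_profiles,
    consensus_hits,
    dendrogram_newick,
    encode_outcomes,
    summarize,
)
from .io import RawPlateStack, read_raw_stack, write_raw_stack
from .normalize import PatternCorrector, normalize_stack, qc_report
from .simulate import generate_library, generate_screen

log = logging.getLogger("qhtscreen")


def _header(config: ScreenConfig) -> str:
    return f"# qhtscreen {__version__} config={config.digest()} seed={config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: ScreenConfig, **kwargs) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=kwargs.pop("index", False), **kwargs)
    return path


def simulate_stage(config: ScreenConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the synthetic screen; writes raw stacks and the truth table."""
    out = Path(out_dir)
    gen = config.generator
    truth = generate_library(
        gen.n_compounds,
        fractions=gen.fractions,
        cll_samples=config.cll_samples,
        normal_samples=config.normal_samples,
        seed=config.seed,
        sigma_log10=gen.sigma_log10,
    )
    stacks = generate_screen(truth, noise=gen.noise, series=config.series.make(), seed=config.seed)
    raw_dir = out / "raw"
    paths = {}
    for sid, stack in stacks.items():
        paths[sid] = write_raw_stack(stack, raw_dir / f"{sid}.csv")
    truth_path = out / "truth.csv"
    truth_path.parent.mkdir(parents=True, exist_ok=True)
    truth.table.to_csv(truth_path, index=False)
    log.info("simulate: %d compounds x %d samples, seed=%d", gen.n_compounds,
             len(stacks), config.seed)
    return {"raw_dir": raw_dir, "truth": truth_path, **{f"raw/{k}": v for k, v in paths.items()}}


def load_stacks(raw_dir: str | Path, sample_ids: list[str]) -> dict[str, RawPlateStack]:
    raw_dir = Path(raw_dir)
    stacks = {}
    for sid in sample_ids:
        path = raw_dir / f"{sid}.csv"
        if not path.exists():
            raise QhtsError(f"stage load: missing raw stack for sample {sid!r} at {path}")
        stacks[sid] = read_raw_stack(path, sample_id=sid)
    return stacks


def run_pipeline(
    config: ScreenConfig,
    out_dir: str | Path,
    raw_dir: str | Path | None = None,
) -> dict[str, Path]:
    """Run the full analysis; simulates the screen when no raw data is given.

    Returns a mapping of artifact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if raw_dir is None:
        artifacts.update(simulate_stage(config, out))
        raw_dir = artifacts["raw_dir"]

    sample_ids = list(config.cll_samples) + list(config.normal_samples)
    stacks = load_stacks(raw_dir, sample_ids)

    qc_parts, norm_parts = [], []
    for sid, stack in stacks.items():
        try:
            corrected = PatternCorrector().fit(stack).transform(stack)
        except QhtsError as exc:
            raise QhtsError(f"stage pattern_correct failed for sample {sid!r}: {exc}") from exc
        qc = qc_report(corrected)
        qc.insert(0, "sample_id", sid)
        qc_parts.append(qc)
        norm_parts.append(normalize_stack(corrected))
    qc_all = pd.concat(qc_parts, ignore_index=True)
    normalized = pd.concat(norm_parts, ignore_index=True)
    artifacts["qc"] = _write_csv(qc_all, out / "qc.csv", config)
    artifacts["normalized"] = _write_csv(normalized, out / "normalized.csv", config)
    log.info("qc: %d plates, median Z'=%.3f, median S/B=%.2f",
             len(qc_all), qc_all["z_factor"].median(), qc_all["sb_ratio"].median())

    curves = (
        normalized[normalized["role"] == plates.ROLE_COMPOUND]
        .loc[:, ["compound_id", "sample_id", "conc_uM", "value_norm"]]
        .rename(columns={"value_norm": "response"})
        .reset_index(drop=True)
    )
    th = config.thresholds
    fits = fit_table(curves, hill_bounds=(0.3, 10.0))
    classifier = CurveClassifier(
        act_threshold=th.act_threshold,
        efficacy_high=th.efficacy_high,
        efficacy_active=th.efficacy_active,
        r2_min=th.r2_min,
        plateau_tol=th.plateau_tol,
    )
    classified = classifier.predict(fits, curves)
    artifacts["fits"] = _write_csv(classified, out / "fits.csv", config)
    log.info("fit+classify: %d curves", len(classified))

    matrix = activity_matrix_from_fits(classified)
    hits = consensus_hits(matrix, config.cll_samples, ic50_gate_uM=th.ic50_gate_uM)
    hits_df = pd.DataFrame(
        [
            {
                "compound_id": h.compound_id,
                "gm_ic50_uM": h.gm_ic50_uM,
                "min_ic50_uM": h.min_ic50_uM,
                "max_ic50_uM": h.max_ic50_uM,
            }
            for h in hits
        ]
    )
    artifacts["consensus_hits"] = _write_csv(hits_df, out / "consensus_hits.csv", config)

    if hits:
        selectivity = call_selectivity(
            matrix, hits, config.normal_samples, curves=curves,
            fold_shift_gate=th.fold_shift_gate, efficacy_diff_gate=th.efficacy_diff_gate,
            cll_samples=config.cll_samples,
        )
    else:
        selectivity = []
    sel_df = pd.DataFrame([vars(s) for s in selectivity]) if selectivity else pd.DataFrame(
        columns=["compound_id", "fold_shift", "efficacy_diff", "n_normal_inactive",
                 "n_normal", "selective"]
    )
    artifacts["selectivity"] = _write_csv(sel_df, out / "selectivity.csv", config)
    log.info("hits: %d consensus, %d selective", len(hits),
             int(sel_df["selective"].sum()) if len(sel_df) else 0)

    summary = summarize(matrix, hits, selectivity, config.cll_samples)
    summary["meta"] = {
        "qhtscreen_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "aggregate_z_factor": round(float(qc_all["z_factor"].median()), 3),
        "aggregate_sb_ratio": round(float(qc_all["sb_ratio"].median()), 3),
        "n_plates": int(len(qc_all)),
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    artifacts["summary"] = summary_path

    codes = encode_outcomes(matrix)
    cluster_ids = [h.compound_id for h in hits] if len(hits) >= 2 else list(codes.index)
    result = cluster_profiles(codes.loc[cluster_ids])
    heatmap_path = out / "heatmap.tsv"
    with open(heatmap_path, "w") as fh:
        fh.write(_header(config))
        result.codes.to_csv(fh, sep="\t")
    artifacts["heatmap"] = heatmap_path
    nwk_path = out / "dendrogram.nwk"
    nwk_path.write_text(dendrogram_newick(result) + "\n")
    artifacts["dendrogram"] = nwk_path
    return artifacts
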