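"""One-shot pipeline wiring and the bundled self-test scenario.

``run_pipeline`` executes the stages trim -> features -> (label -> train)? ->
mask -> align -> denoise -> assess on an input SFF plus reference FASTA,
logging parameters and input/output counts per stage.

``default_scenario`` builds the miniature end-to-end study used by the
self-test and the examples: 10 generated references (length 350, 10%
pairwise divergence, log-uniform uneven abundances), 2,000 simulated
flowgram reads at the default error model, classifier training on the
simulated ground truth with the published balancing protocol, masking,
mask-aware preclustering, and error-rate assessment before and after.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from pyrodenoise import classifier as clf
from pyrodenoise import denoise as dn
from pyrodenoise.assess import compute_error_report
from pyrodenoise.flowgram_io import SeqEntry, read_sequences, read_sff, write_sequences
from pyrodenoise.preprocess import basic_trim, strict_trim_batch
from pyrodenoise.sim454 import SimParams, generate_references, simulate_reads
from pyrodenoise.truth_align import label_reads
from pyrodenoise.errors import StageError


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults; unknown keys are rejected."""

    reads_sff: str = ""
    references_fasta: str = ""
    template_fasta: str = ""  # defaults to the references
    model_path: str = ""
    out_dir: str = "pyrodenoise_out"
    trim_mode: str = "basic"  # basic | strict
    min_len: int = 200
    max_homopolymer: int = 8
    window: int = 100
    q_cutoff: int = 30
    train_model: bool = False
    omega: float = 1.0
    sigma: float = 1.0
    C: float = 1.0
    balance_errors: int = 132
    balance_clean: int = 700
    split_ratio: float = 0.1
    diff_pct: float = 0.02
    chimera_margin: int = 3
    seed: int = 7

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _log(stage: str, **info) -> None:
    print(f"[{stage}] " + " ".join(f"{k}={v}" for k, v in info.items()), file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a machine-readable summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config)}
    t0 = time.time()
    try:
        reads = read_sff(config.reads_sff)
        _log("input", reads=len(reads))
        refs = read_sequences(config.references_fasta, "fasta") if config.references_fasta else []
        template = (
            read_sequences(config.template_fasta, "aligned-fasta")
            if config.template_fasta
            else refs
        )

        kept, report = basic_trim(reads, config.min_len, config.max_homopolymer)
        _log("trim", mode="basic", **report.as_dict())
        summary["trim_basic"] = report.as_dict()
        if config.trim_mode == "strict":
            kept, sreport = strict_trim_batch(kept, config.window, config.q_cutoff, config.min_len)
            _log("trim", mode="strict", **sreport.as_dict())
            summary["trim_strict"] = sreport.as_dict()

        if config.train_model:
            if not refs:
                raise StageError("training requires references")
            instances, unmatched = label_reads(kept, refs)
            _log("label", instances=len(instances), unmatched_reads=unmatched)
            sets = clf.prepare_training_sets(
                instances,
                ratio=config.split_ratio,
                balance={
                    "insertion": config.balance_errors,
                    "deletion": config.balance_errors,
                    "substitution": config.balance_errors,
                    "clean": config.balance_clean,
                },
                seed=config.seed,
            )
            model = clf.train(sets, config.omega, config.sigma, config.C)
            sens, spec, _ = clf.evaluate(model, sets.subset_b)
            _log("train", subset_a=len(sets.subset_a), subset_b=len(sets.subset_b),
                 sensitivity=round(sens, 4), specificity=round(spec, 4))
            summary["classifier"] = {"sensitivity": sens, "specificity": spec}
            model_path = config.model_path or str(out_dir / "model.json")
            model.save(model_path)
            summary["model_path"] = model_path
        else:
            if not config.model_path:
                raise StageError("mask stage needs a model (set model_path or train_model)")
            model = clf.PukSvmModel.load(config.model_path)

        masks = clf.predict_mask(model, kept)
        _log("mask", reads=len(masks), flagged_positions=sum(len(v) for v in masks.values()))

        corrected, result = dn.denoise_reads(
            [(r.read_id, r.bases) for r in kept], masks, template, config.diff_pct
        )
        _log("denoise", seeds=len(corrected), merges=len(result.merge_log))
        corrected_path = out_dir / "corrected.fasta"
        write_sequences(corrected, corrected_path, "fasta")
        summary["corrected_fasta"] = str(corrected_path)
        summary["n_seeds"] = len(corrected)

        if refs:
            raw_entries = [SeqEntry(r.read_id, r.bases) for r in kept]
            raw_report = compute_error_report(raw_entries, refs, config.chimera_margin)
            den_report = compute_error_report(corrected, refs, config.chimera_margin)
            summary["error_rate_raw"] = raw_report.error_rate
            summary["error_rate_denoised"] = den_report.error_rate
            summary["chimera_pct_raw"] = raw_report.chimera_pct
            _log(
                "assess",
                error_rate_raw=round(raw_report.error_rate, 6),
                error_rate_denoised=round(den_report.error_rate, 6),
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(str(exc)) from exc
    summary["wall_seconds"] = time.time() - t0
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


@dataclass
class ScenarioResult:
    """Everything the default end-to-end scenario computes."""

    references: list[SeqEntry]
    weights: np.ndarray
    reads: list
    truths: list
    kept: list
    instances: object
    sets: object
    model: clf.PukSvmModel
    sensitivity: float
    specificity: float
    confusion: object
    masks: dict[str, set[int]]
    corrected: list[SeqEntry]
    cluster: dn.ClusterResult
    raw_report: object
    denoised_report: object


def default_scenario(
    seed: int = 7,
    n_refs: int = 10,
    ref_len: int = 350,
    divergence: float = 0.10,
    n_reads: int = 2000,
    diff_pct: float = 0.02,
) -> ScenarioResult:
    """The bundled miniature end-to-end study (all randomness from ``seed``)."""
    refs, weights = generate_references(n_refs, ref_len, divergence, seed=seed)
    params = SimParams(n_flows=int(ref_len * 2.6), seed=seed + 1)
    reads, truths = simulate_reads(refs, weights, n_reads, params)
    kept, _ = basic_trim(reads)
    instances, _ = label_reads(kept, refs)
    sets = clf.prepare_training_sets(instances, seed=seed + 2)
    model = clf.train(sets)
    sens, spec, confusion = clf.evaluate(model, sets.subset_b)
    masks = clf.predict_mask(model, kept)
    raw_report = compute_error_report([SeqEntry(r.read_id, r.bases) for r in kept], refs)
    corrected, cluster = dn.denoise_reads(
        [(r.read_id, r.bases) for r in kept], masks, refs, diff_pct
    )
    denoised_report = compute_error_report(corrected, refs)
    return ScenarioResult(
        references=refs,
        weights=weights,
        reads=reads,
        truths=truths,
        kept=kept,
        instances=instances,
        sets=sets,
        model=model,
        sensitivity=sens,
        specificity=spec,
        confusion=confusion,
        masks=masks,
        corrected=corrected,
        cluster=cluster,
        raw_report=raw_report,
        denoised_report=denoised_report,
    )


def selftest(
    seed: int = 7,
    verbose: bool = True,
    scenario: ScenarioResult | None = None,
) -> tuple[bool, list[tuple[str, bool, str]]]:
    """Run the bundled scenario and its oracle checks; returns (ok, rows)."""
    sc = scenario if scenario is not None else default_scenario(seed=seed)
    rows: list[tuple[str, bool, str]] = []

    def check(name: str, ok: bool, detail: str) -> None:
        rows.append((name, bool(ok), detail))

    from pyrodenoise.features import FEATURE_COLUMNS

    check("feature schema", len(FEATURE_COLUMNS) == 13, f"{len(FEATURE_COLUMNS)} attributes")
    check(
        "classifier sensitivity >= 0.5",
        sc.sensitivity >= 0.5,
        f"sensitivity={sc.sensitivity:.3f}",
    )
    check(
        "classifier specificity >= 0.9",
        sc.specificity >= 0.9,
        f"specificity={sc.specificity:.3f}",
    )
    raw = sc.raw_report.error_rate
    den = sc.denoised_report.error_rate
    reduction = 100.0 * (raw - den) / raw if raw else 0.0
    check("denoised error rate < raw", den < raw, f"raw={raw:.5f} denoised={den:.5f}")
    check("relative error reduction >= 40%", reduction >= 40.0, f"reduction={reduction:.1f}%")
    total_in = sum(1 for _ in sc.kept)
    total_out = sum(e.abundance for e in sc.corrected)
    check("abundance conservation", total_in == total_out, f"in={total_in} out={total_out}")

    ok = all(r[1] for r in rows)
    if verbose:
        for name, passed, detail in rows:
            print(f"{'PASS' if passed else 'FAIL'}  {name:40s} {detail}")
    return ok, rows
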