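"""End-to-end QC report: filter → base calls → k-mer tests → KL → bootstrap.

The recommended workflow runs the cheap screens first (base-call
profile), then the positional k-mer tests, then the KL-divergence
analysis, optionally calibrated against the simulated null. The bundle
is written as TSV tables plus one JSON summary with headline flags; the
exit status of the CLI reflects execution success only, never the QC
verdict, so pipelines can distinguish "crashed" from "biased data".
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .basecalls import basecall_fractions, count_basecalls, quality_profile
from .divergence import DEFAULT_ALPHA, first_position_excess, kl_matrix
from .filters import filter_artefacts
from .io import Read, ReadSetSummary, read_fasta, read_fastq, write_fastq
from .kmers import (
    background_from_reads,
    background_from_reference,
    count_kmers_by_position,
    results_to_frame,
    test_positional_kmers,
)
from .simulate import ErrorProfile, calibrate_null, effect_sizes

log = logging.getLogger("readbias")

BONFERRONI_ALPHA = 0.01
FIRST_POSITION_RATIO_FLAG = 2.0
MAX_Z_FLAG = 4.0


@dataclass
class RunConfig:
    """Settings for a full QC run."""

    fastq: Path
    outdir: Path
    reference: Path | None = None
    k: int = 6
    alpha: float = DEFAULT_ALPHA
    offset: int | str = "auto"
    min_coverage: int = 1000
    primer: str | None = None
    primer_max_mismatch: int = 1
    polya_max_nonA: int | None = None
    bootstrap_replicates: int = 0  # 0 disables calibration
    seed: int = 0
    test_positions: str = "start"

    def validate(self) -> None:
        if not Path(self.fastq).exists():
            raise FileNotFoundError(f"FASTQ input not found: {self.fastq}")
        if self.reference is not None and not Path(self.reference).exists():
            raise FileNotFoundError(f"reference not found: {self.reference}")


def run_full_report(config: RunConfig, reads: list[Read] | None = None) -> dict[str, Any]:
    """Execute the full pipeline and write the report bundle.

    ``reads`` may be passed directly (already parsed) to skip re-reading
    the FASTQ. Returns the JSON summary as a dict.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"config": {
        k: str(v) if isinstance(v, Path) else v for k, v in vars(config).items()
    }}
    flags: dict[str, bool] = {}

    def stage(name: str):
        log.info("stage %s", name)
        return time.perf_counter()

    # -- parse + filter
    t0 = stage("filter")
    if reads is None:
        rs_summary = ReadSetSummary()
        reads = list(read_fastq(config.fastq, offset=config.offset, summary=rs_summary))
    kept, removed, filt = filter_artefacts(
        reads, primer=config.primer,
        max_mismatch=config.primer_max_mismatch, max_nonA=config.polya_max_nonA,
    )
    if not kept:
        raise RuntimeError("stage filter: no reads left after artefact filtering")
    write_fastq(removed, outdir / "removed.fastq")
    summary["filter"] = {
        "n_input": filt.n_input, "n_kept": filt.n_kept,
        "n_removed_polyA": filt.n_removed_polyA,
        "n_removed_primer": filt.n_removed_primer,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # -- base calls
    t0 = stage("basecalls")
    matrix = count_basecalls(kept)
    qprof = quality_profile(kept)
    frac = basecall_fractions(matrix)
    frac["mean_q"] = np.round(qprof.mean_q, 4)
    frac.to_csv(outdir / "basecalls.tsv", sep="\t")
    summary["basecalls"] = {
        "max_length": matrix.max_length,
        "max_abs_AT_diff": float(np.abs(frac["AT_diff"]).max()),
        "max_abs_CG_diff": float(np.abs(frac["CG_diff"]).max()),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # -- positional k-mer tests
    t0 = stage("kmers")
    table = count_kmers_by_position(kept, config.k)
    reference = None
    if config.reference is not None:
        reference = read_fasta(config.reference)[0]
        background = background_from_reference(reference, config.k, both_strands=True)
    else:
        background = background_from_reads(table)
    results = test_positional_kmers(table, background, positions=config.test_positions)
    df = results_to_frame(results)
    df.to_csv(outdir / "kmer_tests.tsv", sep="\t", index=False)
    flagged = df[df["bonferroni_log10"] <= np.log10(BONFERRONI_ALPHA)]
    flags["start_position_bias"] = not flagged.empty
    summary["kmers"] = {
        "n_tests": len(df),
        "n_flagged": int(len(flagged)),
        "top_kmers": df.head(10)[["kmer", "position", "observed", "expected",
                                  "log10_pvalue", "direction"]].to_dict("records"),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # -- KL divergence
    t0 = stage("kldiv")
    km = kl_matrix(table, alpha=config.alpha, min_coverage=config.min_coverage)
    km.to_frame().to_csv(outdir / "kl_matrix.tsv", sep="\t")
    ratio = first_position_excess(km) if km.n_positions >= 3 else float("nan")
    flags["first_position_divergence"] = bool(ratio > FIRST_POSITION_RATIO_FLAG)
    summary["kldiv"] = {
        "n_positions": km.n_positions,
        "dropped_positions": km.dropped,
        "max_offdiag": float(km.values.max()),
        "first_position_excess_ratio": float(ratio),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # -- bootstrap calibration (optional; needs a reference)
    if config.bootstrap_replicates >= 2 and reference is not None:
        t0 = stage("bootstrap")
        length = max(len(r.seq) for r in kept)
        fixed = [r for r in kept if len(r.seq) == length]
        profile = ErrorProfile.from_quality_profile(quality_profile(fixed))
        cal = calibrate_null(
            reference, n=len(fixed), length=length, profile=profile,
            replicates=config.bootstrap_replicates, k=config.k,
            alpha=config.alpha, seed=config.seed,
        )
        km_fixed = kl_matrix(
            count_kmers_by_position(fixed, config.k), alpha=config.alpha
        )
        es = effect_sizes(km_fixed, cal)
        max_z, argmax = es.max_abs()
        np.savetxt(outdir / "null_mean.tsv", cal.mean, delimiter="\t")
        np.savetxt(outdir / "null_sd.tsv", cal.sd, delimiter="\t")
        np.savetxt(outdir / "effect_z.tsv", es.z, delimiter="\t")
        flags["kl_effect_size_extreme"] = bool(max_z > MAX_Z_FLAG)
        summary["bootstrap"] = {
            "replicates": cal.replicates,
            "avg_sd": cal.avg_sd,
            "avg_sd_ci95": list(cal.avg_sd_ci95),
            "max_abs_z": max_z,
            "argmax_cell": list(argmax),
            "n_degenerate_cells": len(es.degenerate_cells),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    summary["flags"] = flags
    summary["bias_detected"] = any(flags.values())
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
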