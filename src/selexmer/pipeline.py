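"""End-to-end orchestration: simulate or ingest, filter, QC, score, PWM.

A single YAML config drives the run; all outputs land in one directory with
a JSON manifest listing every file by stage. Identical config and seeds
produce byte-identical outputs (no timestamps are written).

Config schema (all keys optional unless noted)::

    design:
      adapter_a: str          # default: Ion A + key adapter, 30 nt
      barcodes: [str, ...]    # default: two 6-nt barcodes
      insert_length: int      # default 12
      adapter_trp1: str       # default: Ion trP1 adapter, 23 nt
    simulate:                 # either this or `inputs` is required
      n_rounds: int           # selection cycles after round 0 (default 3)
      reads_per_round: int    # default 100000
      consensus: str          # planted site (default CACGTG)
      mismatch_factor: float  # per-mismatch penalty lambda (default 5)
      composition_bias: [a, c, g, t]   # round-0 skew
      seed: int               # default 0
    inputs: [fastq, ...]      # one FASTQ per round, index order 0..R
    barcode: str              # sub-library to analyse (default: first barcode)
    ks: [int, ...]            # word sizes to score (default [6, 8, 10])
    background_order: int     # Markov order for long words (default 5)
    background_min_k: int     # use the background for k >= this (default 10)
    outdir: str               # required
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import OligoDesign
from .filtering import filter_reads, filter_report
from .kmers import compute_scores, count_kmers, fit_markov_background
from .pwm import pick_seed, pwm_from_seed, write_meme, write_tabular
from .qc import kld_report
from .simulate import (
    DEFAULT_COMPOSITION_BIAS,
    BindingModel,
    simulate_rounds,
    write_fastq,
)

logger = logging.getLogger("selexmer")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[{stage}] {detail}")


@dataclass
class PipelineConfig:
    outdir: Path
    design: OligoDesign = field(default_factory=OligoDesign)
    simulate: dict | None = None
    inputs: list[Path] | None = None
    barcode: str | None = None
    ks: tuple[int, ...] = (6, 8, 10)
    background_order: int = 5
    background_min_k: int = 10

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.simulate is None and not self.inputs:
            raise ValueError("config must provide either a `simulate` block or `inputs`")
        if self.inputs:
            self.inputs = [Path(p) for p in self.inputs]
            missing = [str(p) for p in self.inputs if not p.exists()]
            if missing:
                raise ValueError(f"input files not found: {missing}")
        if self.barcode is None:
            self.barcode = self.design.barcodes[0]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = OligoDesign(**raw.get("design", {})) if "design" in raw else OligoDesign()
        if "design" in raw and "barcodes" in raw["design"]:
            design = OligoDesign(
                **{**raw["design"], "barcodes": tuple(raw["design"]["barcodes"])}
            )
        return cls(
            outdir=raw.get("outdir", "selexmer_out"),
            design=design,
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            barcode=raw.get("barcode"),
            ks=tuple(raw.get("ks", (6, 8, 10))),
            background_order=int(raw.get("background_order", 5)),
            background_min_k=int(raw.get("background_min_k", 10)),
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "outputs": []}

    def record(stage: str, path: Path) -> None:
        manifest["stages"].setdefault(stage, []).append(str(path))
        manifest["outputs"].append(str(path))

    # --- stage: acquire reads -------------------------------------------
    if config.simulate is not None:
        sim = dict(config.simulate)
        try:
            model = BindingModel(
                consensus=sim.get("consensus", "CACGTG"),
                mismatch_factor=float(sim.get("mismatch_factor", 5.0)),
            )
            rounds = simulate_rounds(
                config.design,
                model,
                n_rounds=int(sim.get("n_rounds", 3)),
                reads_per_round=int(sim.get("reads_per_round", 100_000)),
                composition_bias=sim.get("composition_bias", DEFAULT_COMPOSITION_BIAS),
                rng_seed=int(sim.get("seed", 0)),
                barcode=config.barcode,
            )
            fastqs = write_fastq(rounds, out / "reads")
        except (ValueError, OSError) as e:
            raise PipelineError("simulate", str(e)) from e
        for p in fastqs:
            record("simulate", p)
        logger.info("simulated %d rounds x %d reads", len(fastqs) - 1, len(rounds.rounds[0]))
    else:
        fastqs = list(config.inputs)

    # --- stage: filter ---------------------------------------------------
    filtered = []
    try:
        for r, path in enumerate(fastqs):
            filtered.append(
                filter_reads(path, config.design, config.barcode, round_index=r)
            )
    except (ValueError, OSError) as e:
        raise PipelineError("filter", f"{fastqs[len(filtered)]}: {e}") from e
    report_path = out / "filter_report.tsv"
    filter_report(filtered).to_csv(report_path, sep="\t", index=False)
    record("filter", report_path)
    logger.info(
        "filtered %d rounds; retained %s reads",
        len(filtered),
        [fs.n_retained for fs in filtered],
    )
    if filtered[0].n_retained == 0:
        raise PipelineError("filter", f"no reads retained from round 0 ({fastqs[0]})")

    # --- stage: QC -------------------------------------------------------
    try:
        counts0 = count_kmers(filtered[0], 6)
        rep = kld_report(counts0, label=str(config.barcode))
    except ValueError as e:
        raise PipelineError("qc", str(e)) from e
    qc_path = out / "qc_kld.tsv"
    with open(qc_path, "w") as fh:
        fh.write("library\tk\tkld\tn_windows\n")
        fh.write(f"{rep.label}\t{rep.k}\t{rep.kld:.6f}\t{rep.n_windows}\n")
    record("qc", qc_path)
    logger.info("round-0 KLD_6 = %.4f over %d windows", rep.kld, rep.n_windows)

    # --- stage: count + score -------------------------------------------
    score_tables_by_k = {}
    for k in config.ks:
        try:
            tables = [count_kmers(fs, k) for fs in filtered]
            background = None
            if k >= config.background_min_k:
                background = fit_markov_background(filtered[0], order=config.background_order)
            scores = compute_scores(tables, background=background)
        except ValueError as e:
            raise PipelineError("score", f"k={k}: {e}") from e
        score_tables_by_k[k] = scores
        sparse = k >= 10
        for t, s in zip(tables, scores):
            cpath = out / f"counts_k{k}_round{t.round_index}.tsv"
            t.to_frame(nonzero_only=sparse).to_csv(cpath, sep="\t", index=False)
            record("count", cpath)
            spath = out / f"scores_k{k}_round{s.round_index}.tsv"
            s.to_frame(nonzero_only=sparse).to_csv(
                spath, sep="\t", index=False, float_format="%.6g"
            )
            record("score", spath)

    # --- stage: PWM ------------------------------------------------------
    k_pwm = config.ks[0]
    try:
        last_scores = score_tables_by_k[k_pwm][-1]
        seed = pick_seed(last_scores)
        last_counts = count_kmers(filtered[-1], k_pwm)
        pwm = pwm_from_seed(last_counts, seed)
    except ValueError as e:
        raise PipelineError("pwm", str(e)) from e
    meme_path = write_meme(pwm, out / f"pwm_k{k_pwm}.meme")
    tsv_path = write_tabular(pwm, out / f"pwm_k{k_pwm}.tsv")
    record("pwm", meme_path)
    record("pwm", tsv_path)
    manifest["pwm_seed"] = seed
    logger.info("PWM seed (top %d-mer of last round): %s", k_pwm, seed)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
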