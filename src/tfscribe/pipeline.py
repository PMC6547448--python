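"""End-to-end pipeline: quantify -> expression -> fit -> analyses -> clustering.

A :class:`RunConfig` (plain YAML) names the inputs and knobs; ``run_pipeline``
executes the stages in order, writes TSV/JSON outputs under the run
directory, and finishes with a manifest (config echo, seed, input hashes,
stage outputs).  All randomness derives from the single config seed through
counter-based child seeds, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip, clustering, expression, regulatory, synthetic
from .mars import FitConfig, cv_select

log = logging.getLogger("tfscribe")


class ValidationError(ValueError):
    """Raised with every configuration problem listed at once."""


@dataclass
class RunConfig:
    wig_dir: str = ""
    tss: str = ""
    counts: str = ""
    gene_sets: str | None = None
    out_dir: str = "tfscribe_run"
    conditions: list[str] = field(default_factory=list)
    tfs: list[str] = field(default_factory=list)
    replicates: int = 2
    window_upstream: int = 500
    window_downstream: int = 500
    representation: str = "promoter_sum"
    min_snr: float = 2.0
    endspan: int = 100
    penalty: float = 2.0
    linear_only: bool = False
    max_knot_candidates: int = 64
    cv_folds: int = 5
    cv_repeats: int = 2
    retain_frac: float = 0.5
    cluster_k: str | int = "auto"
    cluster_k_min: int = 2
    cluster_k_max: int = 10
    cluster_restarts: int = 10
    enrich_alpha: float = 0.01
    run_scans: bool = True
    segment_bp: int = 75
    segment_range: tuple[int, int] = (-1000, 1000)
    region_step: int = 50
    region_max_halfwidth: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "segment_range" in raw:
            raw["segment_range"] = tuple(raw["segment_range"])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["segment_range"] = list(d["segment_range"])
        return yaml.safe_dump(d, sort_keys=True)

    def validate(self) -> None:
        errors = []
        for name in ("wig_dir", "tss", "counts"):
            p = getattr(self, name)
            if not p:
                errors.append(f"{name} is required")
            elif not Path(p).exists():
                errors.append(f"{name} path does not exist: {p}")
        if self.gene_sets and not Path(self.gene_sets).exists():
            errors.append(f"gene_sets path does not exist: {self.gene_sets}")
        if not self.conditions:
            errors.append("conditions list is empty")
        if not self.tfs:
            errors.append("tfs list is empty")
        if self.representation not in {"promoter_sum", "peak_window", "peak_signal"}:
            errors.append(f"unknown representation {self.representation!r}")
        for cond in self.conditions:
            for tf in self.tfs:
                for rep in range(1, self.replicates + 1):
                    p = Path(self.wig_dir) / f"{tf}_{cond}_rep{rep}.wig"
                    if not p.exists():
                        errors.append(f"missing coverage track: {p}")
        if errors:
            raise ValidationError("; ".join(errors))

    def fit_config(self) -> FitConfig:
        return FitConfig(endspan=self.endspan, penalty=self.penalty,
                         linear_only=self.linear_only,
                         max_knot_candidates=self.max_knot_candidates)

    def child_seed(self, stage: int) -> int:
        # counter-based fan-out below 2**31
        return int((self.seed * 1009 + stage * 7919) % (2**31 - 1))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_averaged_tracks(config: RunConfig, condition: str) -> dict[str, chip.CoverageTrack]:
    out = {}
    for tf in config.tfs:
        reps = [
            chip.read_wig(Path(config.wig_dir) / f"{tf}_{condition}_rep{r}.wig")
            for r in range(1, config.replicates + 1)
        ]
        out[tf] = chip.average_replicates(reps)
    return out


def quantify_condition(
    config: RunConfig, condition: str, tss: list[chip.TSSRecord],
    tracks: dict[str, chip.CoverageTrack] | None = None,
) -> chip.PromoterSignalMatrix:
    """One condition's genes x TFs matrix in the configured representation."""
    tracks = tracks or _load_averaged_tracks(config, condition)
    window = (config.window_upstream, config.window_downstream)
    per_tf = {}
    for tf, track in tracks.items():
        if config.representation == "promoter_sum":
            per_tf[tf] = chip.promoter_sum(track, tss, window)
        else:
            peaks = chip.annotate_peaks(
                chip.detect_peaks(track, min_snr=config.min_snr), tss,
                radius_bp=max(window),
            )
            if config.representation == "peak_window":
                per_tf[tf] = chip.peak_window_sum(track, peaks, tss)
            else:
                per_tf[tf] = chip.peak_signal_sum(peaks, tss)
    return chip.build_signal_matrix(per_tf, condition, window, config.representation)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": yaml.safe_load(config.to_yaml()),
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }
    for name in ("tss", "counts", "gene_sets"):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    stage = _StageRunner(manifest, out)

    tss = chip.read_tss_table(config.tss)

    # --- quantify ---------------------------------------------------------
    with stage("quantify"):
        tracks_by_cond = {c: _load_averaged_tracks(config, c) for c in config.conditions}
        binding = {}
        for cond in config.conditions:
            mat = quantify_condition(config, cond, tss, tracks_by_cond[cond])
            path = out / f"binding_{cond}.tsv"
            mat.to_tsv(path)
            binding[cond] = mat
            stage.output(path)

    # --- expression -------------------------------------------------------
    with stage("expression"):
        counts = expression.read_counts_table(config.counts)
        counts = expression.filter_min_count(counts, min_reads=1)
        fpkm = expression.compute_fpkm(counts)
        fpkm = fpkm[[c for c in config.conditions if c in fpkm.columns]]
        path = out / "fpkm.tsv"
        fpkm.to_csv(path, sep="\t", index_label="gene_id")
        stage.output(path)

    genes = [g for g in fpkm.index if all(g in b.genes for b in binding.values())]
    fpkm = fpkm.loc[genes]

    # --- fit --------------------------------------------------------------
    models = {}
    with stage("fit"):
        cfg = config.fit_config()
        for i, cond in enumerate(config.conditions):
            X = binding[cond].values.loc[genes]
            y = fpkm[cond]
            m = cv_select(X, y, cfg, folds=config.cv_folds, repeats=config.cv_repeats,
                          retain_frac=config.retain_frac, seed=config.child_seed(100 + i))
            models[cond] = m
            path = out / f"model_{cond}.json"
            path.write_text(m.to_json())
            stage.output(path)

    # --- regulatory analyses ---------------------------------------------
    with stage("regulatory"):
        rows = []
        reports = {}
        for i, cond in enumerate(config.conditions):
            X = binding[cond].values.loc[genes]
            y = fpkm[cond]
            report = regulatory.collinearity(X)
            reports[cond] = report
            report.r.to_csv(out / f"collinearity_r_{cond}.tsv", sep="\t")
            report.p.to_csv(out / f"collinearity_p_{cond}.tsv", sep="\t")
            stage.output(out / f"collinearity_r_{cond}.tsv")
            stage.output(out / f"collinearity_p_{cond}.tsv")
            for s in regulatory.tf_importance(models[cond], X, y, condition=cond,
                                              penalty=config.penalty):
                rows.append({"condition": s.condition, "tf": s.tf, "score": s.score})
            inter = regulatory.interaction_scan(X, y, report)
            pd.DataFrame(
                [
                    {
                        "tf_a": r.tf_a, "tf_b": r.tf_b,
                        "r2_additive": r.r2_additive,
                        "r2_multiplicative": r.r2_multiplicative,
                        "delta_r2": r.delta_r2,
                        "improvement_ratio": r.improvement_ratio,
                        "flagged": r.flagged,
                    }
                    for r in inter
                ]
            ).to_csv(out / f"interactions_{cond}.tsv", sep="\t", index=False)
            stage.output(out / f"interactions_{cond}.tsv")
            subs = regulatory.substitution_test(
                X, y, models[cond], report, config.fit_config(),
                seed=config.child_seed(200 + i),
                folds=config.cv_folds, repeats=1, retain_frac=config.retain_frac,
            )
            (out / f"substitutable_{cond}.json").write_text(json.dumps(subs, indent=1))
            stage.output(out / f"substitutable_{cond}.json")
        pd.DataFrame(rows).to_csv(out / "tf_importance.tsv", sep="\t", index=False)
        stage.output(out / "tf_importance.tsv")

    # --- clustering -------------------------------------------------------
    with stage("clustering"):
        normalized = expression.sum_of_squares_normalize(fpkm)
        if config.cluster_k == "auto":
            curve, k = clustering.select_k_bic(
                normalized, range(config.cluster_k_min, config.cluster_k_max + 1),
                restarts=config.cluster_restarts, seed=config.child_seed(300),
            )
            curve.to_csv(out / "bic_curve.tsv", sep="\t")
            stage.output(out / "bic_curve.tsv")
        else:
            k = int(config.cluster_k)
        cm = clustering.cluster_genes(normalized, k, seed=config.child_seed(301),
                                      restarts=config.cluster_restarts)
        cm.assignments.to_csv(out / "clusters.tsv", sep="\t", index_label="gene_id")
        stage.output(out / "clusters.tsv")
        if config.gene_sets:
            sets = clustering.read_gmt(config.gene_sets)
            res = clustering.enrich(cm, sets, alpha=config.enrich_alpha)
            pd.DataFrame([dataclasses.asdict(r) for r in res]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
            stage.output(out / "enrichment.tsv")
        cluster_binding = {c: binding[c].values.loc[genes] for c in config.conditions}
        pc = clustering.per_cluster_models(
            cm, cluster_binding, fpkm, FitConfig(endspan=config.endspan,
                                                 penalty=config.penalty, linear_only=True),
            seed=config.child_seed(302), folds=config.cv_folds, repeats=config.cv_repeats,
        )
        summary = {
            f"{cl}|{cond}": {
                "r2": d["model"].r2,
                "selected": d["model"].selected_names,
                "importance": {s.tf: s.score for s in d["importance"]},
            }
            for (cl, cond), d in pc.items()
        }
        (out / "cluster_models.json").write_text(json.dumps(summary, indent=1))
        stage.output(out / "cluster_models.json")

    # --- promoter scans ---------------------------------------------------
    if config.run_scans:
        with stage("scans"):
            for cond in config.conditions:
                y = fpkm[cond]
                prof = regulatory.segment_scan(
                    tracks_by_cond[cond], tss_subset(tss, genes), y,
                    segment_bp=config.segment_bp, rel_range=config.segment_range,
                )
                prof.to_csv(out / f"segment_scan_{cond}.tsv", sep="\t")
                stage.output(out / f"segment_scan_{cond}.tsv")
                curve, plateau = regulatory.region_extension_scan(
                    tracks_by_cond[cond], tss_subset(tss, genes), y,
                    step_bp=config.region_step, max_halfwidth=config.region_max_halfwidth,
                    config=FitConfig(endspan=config.endspan, penalty=config.penalty,
                                     linear_only=True),
                )
                curve.to_csv(out / f"region_scan_{cond}.tsv", sep="\t")
                (out / f"region_plateau_{cond}.json").write_text(
                    json.dumps({"halfwidth_bp": plateau})
                )
                stage.output(out / f"region_scan_{cond}.tsv")
                stage.output(out / f"region_plateau_{cond}.json")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def tss_subset(tss: list[chip.TSSRecord], genes) -> list[chip.TSSRecord]:
    gene_set = set(genes)
    return [t for t in tss if t.gene_id in gene_set]


class _StageRunner:
    """Context manager recording stage outputs and timing to stderr logs."""

    def __init__(self, manifest: dict, out_dir: Path):
        self.manifest = manifest
        self.out_dir = out_dir
        self._current: str | None = None

    def __call__(self, name: str) -> "_StageRunner":
        self._current = name
        self.manifest["stages"][name] = {"outputs": []}
        return self

    def output(self, path: Path) -> None:
        self.manifest["stages"][self._current]["outputs"].append(path.name)

    def __enter__(self):
        self._t0 = time.time()
        log.info("stage %s: start", self._current)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            log.error("stage %s: FAILED (%s)", self._current, exc)
            raise StageError(self._current, exc) from exc
        log.info("stage %s: done in %.1fs", self._current, time.time() - self._t0)
        return False


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Demo bundle
# ---------------------------------------------------------------------------

def make_demo(seed: int = 7, out_dir: str | Path = "demo") -> Path:
    """Write a small synthetic bundle (200 genes, 8 TFs, 2 conditions) plus a
    ready-to-run config and the generative-truth record."""
    out = Path(out_dir)
    (out / "wig").mkdir(parents=True, exist_ok=True)
    truth = synthetic.SyntheticTruth(
        n_genes=200,
        n_tfs=8,
        conditions=("condA", "condB"),
        active_tfs=(0, 2, 5),
        coefficients={0: 1.2, 2: 0.9, 5: 0.8},
        knots={0: 8.0},
        collinear_pairs=((2, 3, 0.9),),
        interaction_pair=(0, 2, 0.02),
        intercept=5.0,
        noise_sd=15.0,
        seed=seed,
    )
    bundle = synthetic.generate_bundle(truth)
    tss = synthetic.make_tss_table(truth.gene_ids, spacing=2500)
    chip.write_tss_table(tss, out / "tss.tsv")
    bundle.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
    (out / "truth.json").write_text(truth.to_json())

    for cond in truth.conditions:
        for tf in truth.tf_names:
            tracks = synthetic.binding_to_tracks(
                truth, bundle.binding[cond], tss, tf, background_rate=0.05, replicates=2
            )
            for i, tr in enumerate(tracks, start=1):
                chip.write_wig(tr, out / "wig" / f"{tf}_{cond}_rep{i}.wig")

    # a few gene sets over the demo universe, tied to the planted drivers
    b = bundle.binding[truth.conditions[0]].values
    sets = {}
    for tf_idx in truth.active_tfs:
        tf = truth.tf_names[tf_idx]
        top = b[tf].nlargest(30).index
        sets[f"high_{tf}_binding"] = list(top)
    with open(out / "gene_sets.gmt", "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic demo set"] + list(members)) + "\n")

    config = RunConfig(
        wig_dir=str(out / "wig"),
        tss=str(out / "tss.tsv"),
        counts=str(out / "counts.tsv"),
        gene_sets=str(out / "gene_sets.gmt"),
        out_dir=str(out / "run"),
        conditions=list(truth.conditions),
        tfs=truth.tf_names,
        replicates=2,
        endspan=20,
        cluster_k_max=6,
        region_max_halfwidth=600,
        seed=seed,
    )
    (out / "run.yaml").write_text(config.to_yaml())

    expected = {
        "active_tfs": [truth.tf_names[i] for i in truth.active_tfs],
        "collinear_pairs": [
            [truth.tf_names[a], truth.tf_names[b], rho] for a, b, rho in truth.collinear_pairs
        ],
        "interaction_pair": [
            truth.tf_names[truth.interaction_pair[0]],
            truth.tf_names[truth.interaction_pair[1]],
            truth.interaction_pair[2],
        ],
        "noise_sd": truth.noise_sd,
    }
    (out / "expected.json").write_text(json.dumps(expected, indent=1))
    return out


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper(), logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
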