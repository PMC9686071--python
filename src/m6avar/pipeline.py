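"""End-to-end orchestration: config, stages, manifest and run report.

``run_pipeline`` executes the analysis stages in method order — variability,
enrichment, reproducible peaks, metagene, motif, differential, association —
writing every table under the output directory plus a checksum manifest and
a JSON report of all parameters and headline statistics. Re-running with the
same config reproduces every output byte-identically (the log file carries
no timestamps for that reason).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association_stats as assoc
from . import methylation, metagene, motif, variability
from .formats_io import (
    GroupKey,
    logger,
    read_expression,
    read_gene_models,
    read_peaks,
)

REFERENCE_MOTIF_GROUP = GroupKey("leaf", "CS", "wt")  # non-stressed leaf sample


@dataclass
class RunConfig:
    gtf: str
    fasta: str
    expression: str
    peaks: dict[str, list[str]]  # "tissue.condition.genotype" -> BED paths (per IP rep)
    outdir: str
    aux_scores: str | None = None
    pseudocount: float = methylation.DEFAULT_PSEUDOCOUNT
    fold_threshold: float = 2.0
    selection_fold: float = 2.0
    hvg_min: float = 5.0
    lvg_max: float = -10.0
    cv_scale: float = 1.0
    min_fpkm: float = 1.0
    bins: int = 100
    smoothing_sigma: float = 2.0
    top_n: int = 1000
    seed: int = 0
    # explicit one-tailed directions, per claim being tested
    alt_differential: str = "greater"  # mutant enrichment vs wt
    alt_variability: str = "less"  # regulated genes' delta-variability vs random
    alt_aux: str = "greater"  # low-variability genes' aux scores vs random
    # thresholds used for the quartile/LVG association readout
    assoc_hvg_min: float | None = None  # defaults to hvg_min

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        missing = []
        for p in [self.gtf, self.fasta, self.expression, *(
            q for paths in self.peaks.values() for q in paths
        )] + ([self.aux_scores] if self.aux_scores else []):
            if not Path(p).is_file():
                missing.append(str(p))
        if missing:
            raise FileNotFoundError("missing input file(s): " + ", ".join(missing))
        for alt in (self.alt_differential, self.alt_variability, self.alt_aux):
            if alt not in ("less", "greater"):
                raise ValueError(f"invalid alternative {alt!r}")
        if self.bins < 10:
            raise ValueError("bins must be >= 10")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_df(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def _setup_log(outdir: Path, level: str = "INFO") -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level)
    return handler


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the report dict (also written as report.json)."""
    config.validate()  # fail fast: nothing written on bad config
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(outdir)
    outputs: list[Path] = []
    report: dict = {"parameters": asdict(config), "stages": {}}
    report["input_checksums"] = {
        Path(p).name: _sha256(Path(p))
        for p in [config.gtf, config.fasta, config.expression]
    }
    stage = "setup"
    try:
        models = read_gene_models(config.gtf)
        expr = read_expression(config.expression)
        peaksets = {
            label: [
                read_peaks(p, GroupKey(*label.split(".")), rep)
                for rep, p in enumerate(paths, start=1)
            ]
            for label, paths in config.peaks.items()
        }

        # --- stage 1: variability ------------------------------------------
        stage = "variability"
        thr = variability.VariabilityThresholds(
            config.hvg_min, config.lvg_max, config.cv_scale, config.min_fpkm
        )
        var_tab = variability.variability_table(expr, thr)
        _write_df(var_tab, outdir / "variability.tsv")
        outputs.append(outdir / "variability.tsv")
        counts = variability.class_counts(var_tab)
        _write_df(counts.reset_index(), outdir / "variability_class_counts.tsv")
        outputs.append(outdir / "variability_class_counts.tsv")
        report["stages"][stage] = {
            "class_counts": {g: row.to_dict() for g, row in counts.iterrows()}
        }

        # --- stage 2: enrichment -------------------------------------------
        stage = "enrichment"
        enr_tab = methylation.enrichment_table(expr, config.pseudocount)
        _write_df(enr_tab, outdir / "enrichment.tsv")
        outputs.append(outdir / "enrichment.tsv")
        meth_counts = methylation.methylated_counts(enr_tab)
        report["stages"][stage] = {"methylated_counts": meth_counts.to_dict()}

        # --- stage 3: reproducible peaks -----------------------------------
        stage = "peaks"
        reproducible: dict[str, object] = {}
        peak_counts = pd.DataFrame(index=list(models))
        for label, reps in sorted(peaksets.items()):
            if len(reps) >= 2:
                rp = methylation.reproducible_peaks(reps[0], reps[1])
            else:
                rp = reps[0]
            reproducible[label] = rp
            bed = outdir / f"reproducible_peaks.{label}.bed"
            rp.write_bed(bed)
            outputs.append(bed)
            peak_counts[label] = methylation.assign_peaks(rp, models).counts
        pc = peak_counts.reset_index().rename(columns={"index": "gene_id"})
        _write_df(pc, outdir / "peak_counts.tsv")
        outputs.append(outdir / "peak_counts.tsv")
        report["stages"][stage] = {
            "n_reproducible": {k: len(v.peaks) for k, v in reproducible.items()}
        }

        # --- stage 4: metagene ---------------------------------------------
        stage = "metagene"
        prof_cols: dict[str, np.ndarray] = {}
        argmax: dict[str, float] = {}
        centers = None
        for label, rp in sorted(reproducible.items()):
            prof = metagene.metagene_density(
                rp, models, bins=config.bins, smoothing_sigma=config.smoothing_sigma
            )
            centers = prof.bin_centers
            prof_cols[label] = prof.density
            argmax[label] = float(centers[int(np.argmax(prof.density))]) if prof.n_peaks else float("nan")
        meta = pd.DataFrame({"bin_center": centers, **prof_cols})
        _write_df(meta, outdir / "metagene.tsv")
        outputs.append(outdir / "metagene.tsv")
        report["stages"][stage] = {"density_argmax": argmax}

        # --- stage 5: motif -------------------------------------------------
        stage = "motif"
        ref_label = REFERENCE_MOTIF_GROUP.label()
        ref_peaks = reproducible.get(ref_label) or next(iter(reproducible.values()))
        top = motif.top_regions(ref_peaks, config.top_n)
        pfm = motif.build_pfm(top, config.fasta, models)
        pfm.to_tsv(outdir / "motif_pfm.tsv")
        outputs.append(outdir / "motif_pfm.tsv")
        (outdir / "motif_pfm.transfac").write_text(pfm.to_transfac())
        outputs.append(outdir / "motif_pfm.transfac")
        report["stages"][stage] = {"support": pfm.support}

        # --- stage 6: differential methylation ------------------------------
        stage = "differential"
        diff_report = {}
        for tissue in ("leaf", "flower"):
            wt = enr_tab[enr_tab["group"] == f"{tissue}.CS.wt"]
            mut = enr_tab[enr_tab["group"] == f"{tissue}.CS.mutant"]
            if wt.empty or mut.empty:
                continue
            diff = methylation.differential_enrichment(wt, mut, config.fold_threshold)
            _write_df(diff, outdir / f"differential.{tissue}.tsv")
            outputs.append(outdir / f"differential.{tissue}.tsv")
            test = assoc.rank_test_one_tailed(
                mut["enrichment"].to_numpy(),
                wt["enrichment"].to_numpy(),
                config.alt_differential,
            )
            diff_report[tissue] = {
                "n_regulated": int(diff["regulated"].sum()),
                "rank_test_p": test.p_value,
            }
        report["stages"][stage] = diff_report

        # --- stage 7: association ------------------------------------------
        stage = "association"
        assoc_report: dict = {}
        # quartile fractions per group (input CV2 quartiles vs methylated call)
        quartile_tabs = []
        for grp in expr.groups("input"):
            label = grp.label()
            try:
                quart = variability.variability_quartiles(var_tab, label)
            except ValueError:
                continue
            meth = methylation.call_methylated(enr_tab, label)
            qt = assoc.fraction_methylated_by_quartile(quart, meth)
            qt.insert(0, "group", label)
            quartile_tabs.append(qt)
            assoc_report.setdefault("quartile_fractions", {})[label] = {
                "fractions": qt["fraction"].round(6).tolist(),
                "monotone_nonincreasing": qt.attrs["monotone_nonincreasing"],
            }
        if quartile_tabs:
            _write_df(
                pd.concat(quartile_tabs, ignore_index=True), outdir / "quartile_fractions.tsv"
            )
            outputs.append(outdir / "quartile_fractions.tsv")
        # heat-FC vs enrichment-change correlation (wt, per tissue)
        assoc_report["fc_correlation"] = {}
        for tissue in ("leaf", "flower"):
            try:
                r, n = assoc.fc_correlation(expr, tissue, "wt", config.pseudocount)
            except KeyError:
                continue
            assoc_report["fc_correlation"][tissue] = {"r": r, "n": n}
        # regulated genes' variability change vs random baseline (flower)
        try:
            delta = variability.variability_difference(
                expr, GroupKey("flower", "CS", "wt"), GroupKey("flower", "CS", "mutant"), thr
            )
            wt = enr_tab[enr_tab["group"] == "flower.CS.wt"]
            mut = enr_tab[enr_tab["group"] == "flower.CS.mutant"]
            diff = methylation.differential_enrichment(wt, mut, config.fold_threshold)
            regulated = set(diff.loc[diff["regulated"], "gene_id"]) & set(delta.index)
            if regulated and len(regulated) <= len(delta) // 2:
                cmp_res = assoc.score_comparison(
                    regulated, delta, config.alt_variability, seed=config.seed
                )
                assoc_report["regulated_variability"] = {
                    "n_regulated": len(regulated),
                    "p": cmp_res.test.p_value,
                }
            _write_df(
                delta.rename_axis("gene_id").reset_index(), outdir / "variability_difference.flower.tsv"
            )
            outputs.append(outdir / "variability_difference.flower.tsv")
        except KeyError:
            pass
        # auxiliary score comparison (e.g. stress-granule scores of LVGs)
        if config.aux_scores:
            aux = pd.read_csv(config.aux_scores, sep="\t", index_col=0)["score"]
            meth_flower = methylation.call_methylated(enr_tab, "flower.CS.wt") & set(aux.index)
            if meth_flower and len(meth_flower) <= len(aux) // 2:
                res = assoc.score_comparison(
                    meth_flower, aux, config.alt_aux, seed=config.seed
                )
                assoc_report["aux_score_comparison"] = {
                    "n_set": len(meth_flower),
                    "p": res.test.p_value,
                }
        # heat-response matrix
        heat = assoc.heat_response_matrix(expr, config.selection_fold, config.pseudocount)
        _write_df(heat.rename_axis("gene_id").reset_index(), outdir / "heat_response_matrix.tsv")
        outputs.append(outdir / "heat_response_matrix.tsv")
        assoc_report["heat_column_means"] = {
            k: float(v) for k, v in heat.attrs["column_means"].items()
        }
        assoc_report["n_heat_selected"] = int(len(heat))
        report["stages"][stage] = assoc_report
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        if handler in logger.handlers:
            logger.removeHandler(handler)
            handler.close()

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
    outputs.append(report_path)
    manifest = pd.DataFrame(
        [(p.name, _sha256(p)) for p in sorted(outputs)], columns=["file", "sha256"]
    )
    _write_df(manifest, outdir / "manifest.tsv")
    return report
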