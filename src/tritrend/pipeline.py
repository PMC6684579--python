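"""Full-run orchestration: normalize -> three contrasts -> classify -> enrich.

The full pipeline runs the three contrasts (L vs H, NL vs H, NL vs L) on the
intensity and spectral-count matrices, classifies every protein with the
trend taxonomy, writes per-contrast result tables, the flags table, a
category summary and a reproducibility manifest (config, seeds, package
version, input checksums).  Rerunning with the same inputs and seed
reproduces all outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_tables import (
    AbundanceMatrix,
    ContrastCall,
    SampleDesign,
    TriContrast,
    ValidationError,
    read_abundance_table,
)
from .diffexpr import ContrastSpec, run_contrast
from .trend_classify import TrendClassifier, summarize_categories
from .enrichment import ora
from .io_tables import read_gmt

logger = logging.getLogger("tritrend")

CONTRASTS = (
    ContrastSpec("L", "H"),
    ContrastSpec("NL", "H"),
    ContrastSpec("NL", "L"),
)
_SHORT = {"L_vs_H": "LH", "NL_vs_H": "NLH", "NL_vs_L": "NLL"}


@dataclass
class RunConfig:
    """Everything a full run needs; serialized into the manifest."""

    intensity_path: str | None = None
    counts_path: str | None = None
    design_path: str | None = None
    out_dir: str = "tritrend_run"
    alpha: float = 0.05
    fc_threshold: float = 2.0
    pseudocount: float = 0.5
    min_obs: int = 2
    normalization: str = "total_sum"
    n_permutations: int = 1000
    seed: int = 0
    gmt_path: str | None = None
    min_term_size: int = 3
    max_term_size: int = 500

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValidationError("fc_threshold must be > 1")
        if self.normalization not in ("none", "total_sum"):
            raise ValidationError("normalization must be 'none' or 'total_sum'")


def normalize_total(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Total-sum scaling: each column's observed sum becomes the median sum.

    Corrects per-sample loading/acquisition differences while keeping values
    on the original scale; missingness is preserved.  A column with no
    observed values is an error.
    """
    values = matrix.values
    sums = values.sum(axis=0, skipna=True)
    n_obs = values.notna().sum(axis=0)
    empty = n_obs[n_obs == 0]
    if len(empty):
        raise ValidationError(f"column(s) with no observed values: {list(empty.index)}")
    target = float(np.median(sums.to_numpy()))
    scaled = values * (target / sums)
    scaled.attrs["derived"] = True
    return AbundanceMatrix(values=scaled, design=matrix.design)


def assemble_tricontrasts(
    res_lh: pd.DataFrame, res_nlh: pd.DataFrame, res_nll: pd.DataFrame
) -> list[TriContrast]:
    """Join the three per-contrast result tables into classifier input."""
    ids = res_lh.index
    if not (ids.equals(res_nlh.index) and ids.equals(res_nll.index)):
        raise ValidationError("contrast results do not share the same protein ids")

    def call(df: pd.DataFrame, pid: str) -> ContrastCall:
        row = df.loc[pid]
        fc = row["fc_ratio"]
        return ContrastCall(
            fc_ratio=None if pd.isna(fc) else float(fc),
            significant=bool(row["significant"]),
        )

    return [
        TriContrast(
            protein_id=str(pid),
            lh=call(res_lh, pid),
            nlh=call(res_nlh, pid),
            nll=call(res_nll, pid),
        )
        for pid in ids
    ]


def run_contrasts(
    intensity: AbundanceMatrix,
    counts: AbundanceMatrix | None,
    config: RunConfig,
) -> dict[str, pd.DataFrame]:
    """The three contrasts with per-contrast derived seeds."""
    results = {}
    for i, contrast in enumerate(CONTRASTS):
        seed = (config.seed * 7919 + i) % (2**31)
        logger.info("contrast %s (seed %d)", contrast.name, seed)
        results[_SHORT[contrast.name]] = run_contrast(
            intensity,
            counts,
            contrast,
            alpha=config.alpha,
            fc_threshold=config.fc_threshold,
            pseudocount=config.pseudocount,
            min_obs=config.min_obs,
            n_permutations=config.n_permutations,
            seed=seed,
        )
    return results


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(
    config: RunConfig,
    intensity: AbundanceMatrix | None = None,
    counts: AbundanceMatrix | None = None,
) -> Path:
    """Execute the whole pipeline and write a run directory.

    Matrices may be passed in memory (e.g. from the simulator) or read from
    the paths in ``config``.  Returns the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    input_checksums = {}
    if intensity is None:
        if config.intensity_path is None or config.design_path is None:
            raise ValidationError("intensity_path and design_path are required")
        intensity = read_abundance_table(
            config.intensity_path, config.design_path, channel="intensity"
        )
        input_checksums["intensity"] = _sha256(config.intensity_path)
        input_checksums["design"] = _sha256(config.design_path)
    if counts is None and config.counts_path is not None:
        counts = read_abundance_table(
            config.counts_path, config.design_path, channel="spectral_count"
        )
        input_checksums["counts"] = _sha256(config.counts_path)

    intensity.design.require_conditions()
    if config.normalization == "total_sum":
        logger.info("total-sum normalization")
        intensity = normalize_total(intensity)
        if counts is not None:
            counts = normalize_total(counts)

    results = run_contrasts(intensity, counts, config)
    for key, df in results.items():
        df.to_csv(out / f"results_{key}.tsv", sep="\t", na_rep="")

    tcs = assemble_tricontrasts(results["LH"], results["NLH"], results["NLL"])
    flags = TrendClassifier(fc_threshold=config.fc_threshold).fit_transform(tcs)
    flags["log2fc_LH"] = results["LH"]["log2fc"]
    flags["log2fc_NLH"] = results["NLH"]["log2fc"]
    flags["log2fc_NLL"] = results["NLL"]["log2fc"]
    flags.to_csv(out / "flags.tsv", sep="\t", na_rep="")

    summary = summarize_categories(flags)
    pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t", index=False, na_rep="")

    if config.gmt_path is not None:
        annotations = read_gmt(config.gmt_path)
        background = list(intensity.protein_ids)
        de_lh = flags.index[flags["de_LH"].astype(bool)].tolist()
        if de_lh:
            enr = ora(
                de_lh, background, annotations,
                min_term_size=config.min_term_size,
                max_term_size=config.max_term_size,
            )
            enr.to_csv(out / "enrichment_LH.tsv", sep="\t", index=False)
        else:
            logger.warning("no L-vs-H DE proteins; enrichment skipped")

    manifest = {
        "package": "tritrend",
        "version": __version__,
        "config": asdict(config),
        "contrast_seeds": {
            _SHORT[c.name]: (config.seed * 7919 + i) % (2**31)
            for i, c in enumerate(CONTRASTS)
        },
        "input_checksums": input_checksums,
        "n_proteins": intensity.n_proteins,
        "summary": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in summary.items()},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out)
    return out
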