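"""End-to-end orchestration: VCFs -> profiles -> features -> predictions.

``run_pipeline`` wires the modules together for a batch of samples and
writes deterministic TSV outputs plus a machine-readable run manifest
(inputs, seed, thresholds, package version), so a run can be reproduced
byte-for-byte from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .classifier import TrainedScarModel, apply_qc, predictions_to_frame
from .config import Thresholds, DEFAULT_THRESHOLDS
from .contexts import extract_profile, MutationContextProfile
from .features import build_feature_table
from .formats import (
    FastaReferenceStore,
    read_small_variant_vcf,
    read_sv_vcf,
    write_profile_tsv,
)

log = logging.getLogger("hrdscar")


@dataclass
class SampleInput:
    """Paths for one sample's somatic calls."""

    name: str
    vcf: str
    sv_vcf: Optional[str] = None


def run_pipeline(
    samples: Sequence[SampleInput | Mapping],
    reference: str,
    out_dir: str,
    model: TrainedScarModel | str | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    seed: int = 0,
) -> dict:
    """Extract profiles and features for a batch of samples; if a trained
    model is supplied, predict and attach QC flags.

    Writes ``profiles.tsv``, ``features.tsv``, optionally
    ``predictions.tsv``, and ``manifest.json`` under ``out_dir``; returns
    the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = [
        s if isinstance(s, SampleInput) else SampleInput(**s) for s in samples
    ]
    if isinstance(model, str):
        model = TrainedScarModel.load(model)

    genome = FastaReferenceStore(reference)
    profiles: dict[str, MutationContextProfile] = {}
    skip_log: dict[str, int] = {}
    for s in samples:
        small, n_skip_vcf = read_small_variant_vcf(s.vcf)
        svs, n_skip_sv = ([], 0)
        if s.sv_vcf:
            svs, n_skip_sv = read_sv_vcf(s.sv_vcf)
        profile = extract_profile(small, svs, genome, thresholds)
        profiles[s.name] = profile
        skip_log[s.name] = n_skip_vcf + n_skip_sv + profile.n_skipped
        log.info(
            "%s: %d contexts counted, %d records skipped",
            s.name,
            profile.total(),
            skip_log[s.name],
        )

    write_profile_tsv(profiles, out / "profiles.tsv")
    features = build_feature_table(profiles)
    features.rename_axis("sample").to_csv(out / "features.tsv", sep="\t")

    manifest = {
        "version": __version__,
        "seed": seed,
        "thresholds": thresholds.as_dict(),
        "reference": str(reference),
        "samples": [
            {"name": s.name, "vcf": s.vcf, "sv_vcf": s.sv_vcf} for s in samples
        ],
        "skipped_records": skip_log,
        "outputs": ["profiles.tsv", "features.tsv"],
    }

    if model is not None:
        preds = model.predict(features)
        preds = [
            type(p)(
                sample=p.sample,
                p_brca1=p.p_brca1,
                p_brca2=p.p_brca2,
                p_none=p.p_none,
                cutoff=p.cutoff,
                qc_flags=apply_qc(profiles[p.sample], p, thresholds),
            )
            for p in preds
        ]
        predictions_to_frame(preds).to_csv(out / "predictions.tsv", sep="\t")
        manifest["outputs"].append("predictions.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
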