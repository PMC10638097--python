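"""End-to-end orchestration: response -> confidence -> filters -> morphometrics.

The stage order is fixed; each stage after the raw response is a pure
mask, so the retained voxel count recorded in the run manifest is
monotone non-increasing:

1. windowed Spearman response with intensity gating,
2. bleed-through z-score mask (both channels),
3. per-voxel confidence (significance + minimum observable correlation),
4. shadow (third-derivative consistency) filter,
5. 26-connected labelling with minimum-size removal,
6. mitochondria/vesicle adjacency filter,

followed by per-contact features, sliding-window coverage statistics and
the large-contact (Q95) summary.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import confidence as conf
from . import diffgeom, filters, quantify
from .response import ResponseMap, contact_response
from .volume_io import DetectParams, VolumePair, write_outputs

logger = logging.getLogger("contactsites")

STAGES = (
    "response_gating",
    "bleedthrough",
    "confidence",
    "shadow",
    "min_size",
    "vesicle_filter",
)


@dataclass
class RunManifest:
    """Provenance record of one detection run."""

    params: dict
    stage_voxels: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = ""

    def record(self, stage: str, magnitude_or_mask: np.ndarray, t0: float) -> None:
        count = int(np.count_nonzero(magnitude_or_mask))
        self.stage_voxels[stage] = count
        self.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %-16s retained %d voxels", stage, count)

    def assert_monotone(self) -> None:
        counts = [self.stage_voxels[s] for s in STAGES if s in self.stage_voxels]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise AssertionError(f"stage voxel counts not monotone: {counts}")

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "stage_voxels": self.stage_voxels,
            "stage_seconds": self.stage_seconds,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "version": self.version,
        }


@dataclass
class RunResult:
    response: ResponseMap
    contacts: quantify.ContactSet
    mito: filters.MitoComponents
    features: pd.DataFrame
    windows: pd.DataFrame
    summary: dict
    manifest: RunManifest


def run_detect(pair: VolumePair, params: DetectParams | None = None) -> RunResult:
    """Run the full detection and quantification pipeline on one volume pair."""
    params = params or DetectParams()
    manifest = RunManifest(params=params.to_dict())
    manifest.inputs["shape"] = list(pair.shape)
    manifest.inputs["spacing_nm"] = list(pair.spacing)
    from . import __version__

    manifest.version = __version__

    t0 = time.perf_counter()
    resp = contact_response(pair, params)
    manifest.record("response_gating", resp.magnitude, t0)

    t0 = time.perf_counter()
    resp = filters.apply_bleedthrough(
        resp, pair.channel_a, pair.channel_b, params.z_filter
    )
    manifest.record("bleedthrough", resp.magnitude, t0)

    t0 = time.perf_counter()
    resp = conf.apply_confidence(resp, params)
    manifest.record("confidence", resp.magnitude, t0)

    t0 = time.perf_counter()
    spacing = pair.spacing if params.physical_units else None
    d3a = diffgeom.third_derivative(pair.channel_a, spacing=spacing, source_channel="a")
    d3b = diffgeom.third_derivative(pair.channel_b, spacing=spacing, source_channel="b")
    resp = filters.shadow_filter(resp, d3a, d3b)
    manifest.record("shadow", resp.magnitude, t0)

    t0 = time.perf_counter()
    contacts = quantify.label_contacts(resp.magnitude, params.min_contact_voxels)
    manifest.record("min_size", contacts.labels, t0)

    t0 = time.perf_counter()
    mito = filters.segment_mito_components(
        pair.channel_b, params.mito_ln_size, params.mito_min_intensity
    )
    filtered_labels, survivors = filters.vesicle_filter(contacts.labels, mito)
    contacts = quantify.ContactSet(
        filtered_labels,
        contacts.volumes[contacts.volumes.label.isin(survivors)].reset_index(
            drop=True
        ),
    )
    resp = resp.copy_with_magnitude(
        np.where(contacts.labels > 0, resp.magnitude, 0.0)
    )
    manifest.record("vesicle_filter", contacts.labels, t0)
    manifest.assert_monotone()

    features = quantify.contact_features(contacts, resp, pair.spacing)
    windows = quantify.sliding_window_stats(contacts, mito, params.quant_k)
    summary = {
        "n_contacts": contacts.n_contacts,
        "rho_min": conf.min_detectable_rho(
            params.n_window, params.alpha, params.power, params.plain_variance
        ),
        **{f"cell_{k}": v for k, v in quantify.window_summary(windows).items()},
        **quantify.q95_summary(contacts, params.large_contact_voxels),
        "stage_voxels": manifest.stage_voxels,
    }
    return RunResult(resp, contacts, mito, features, windows, summary, manifest)


def run_and_write(
    pair: VolumePair, params: DetectParams, out_dir
) -> tuple[RunResult, dict]:
    """Run the pipeline and write all result artifacts to ``out_dir``."""
    result = run_detect(pair, params)
    file_manifest = write_outputs(
        out_dir,
        params,
        magnitude=result.response.magnitude,
        contact_mask=result.contacts.mask(),
        contacts_table=result.features,
        windows_table=result.windows,
        summary=result.summary,
    )
    result.manifest.outputs = file_manifest["files"]
    return result, file_manifest
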