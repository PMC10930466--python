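"""Shared fixtures: phantoms, layouts, and one full recovery run."""

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def disk_phantom():
    """400 um field with a 140 um tumor disk in stroma (50 um interface)."""
    from spatialfuse import phantom as ph

    cfg = ph.PhantomConfig(
        seed=7,
        field_size_um=(400.0, 400.0),
        compartment_spec={
            "background": "stroma",
            "disks": [{"compartment": "tumor", "center": (200.0, 200.0), "radius": 140.0}],
            "interface_halfwidth_um": 50.0,
        },
    )
    return ph.make_phantom(cfg)


@pytest.fixture(scope="session")
def small_layout():
    """20 x 20 spot grid at 2 um pitch with enforced barcode separation."""
    from spatialfuse import phantom as ph

    return ph.emit_chip_layout(20, 20, pitch_um=2.0, seed=5)


@pytest.fixture(scope="session")
def recovery_run():
    """End-to-end planted-compartment recovery at realistic bin depth.

    Equal-area tumor/stroma geometry, three sections, ~500 UMIs per bin
    (the scale of the chip QC tables), clustered at default settings.
    Shared across cluster-recovery and marker-selection tests.
    """
    from spatialfuse import phantom as ph
    from spatialfuse import spatial_tx as stx
    from spatialfuse.stereo_reads import build_matrix, process_read_pairs

    cfg = ph.PhantomConfig(
        seed=11,
        field_size_um=(800.0, 800.0),
        compartment_spec={
            "background": "stroma",
            "disks": [{"compartment": "tumor", "center": (400.0, 400.0), "radius": 319.0}],
            "interface_halfwidth_um": 50.0,
        },
        barcode_error_rate=0.0,
        mid_lowq_rate=0.0,
    )
    phantom = ph.make_phantom(cfg)
    layout = ph.emit_chip_layout(
        200, 200, pitch_um=4.0, seed=11, enforce_hamming_max_n=0
    )
    binned = []
    for sec in range(3):
        reads = ph.emit_stereo_reads(phantom, sec, layout, depth=5)
        matrix = build_matrix(
            process_read_pairs(reads.pairs(), layout, phantom.reference),
            layout,
            phantom.reference,
            section=sec,
        )
        binned.append(stx.bin_spots(matrix, 10))
    filtered = [stx.qc_filter(b) for b in binned]
    merged = stx.preprocess(filtered, merge=True)
    merged = stx.cluster(merged, seed=0)
    return phantom, merged
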