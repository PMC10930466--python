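"""Phantom generator: geometry, determinism, emission statistics."""

import numpy as np
import pandas as pd
import pytest

from spatialfuse import phantom as ph
from spatialfuse.reference import ConfigurationError


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class TestMakePhantom:
    def test_single_compartment_constant_field(self):
        cfg = ph.PhantomConfig(
            seed=0,
            field_size_um=(100.0, 100.0),
            compartment_spec={"background": "stroma", "disks": []},
            gene_programs={"stroma": {"G0": 1.0, "G1": 1.0}},
            analyte_maps={"stroma": {100.0: 1.0}},
            phenotypes=(ph.PhenotypeSpec("immune", {"CD45": 1.0}, ("stroma",)),),
        )
        p = ph.make_phantom(cfg)
        assert (p.compartment_field == 0).all()
        assert not p.interface_mask.any()

    def test_same_seed_identical(self):
        cfg = ph.PhantomConfig(seed=42, field_size_um=(200.0, 200.0))
        a, b = ph.make_phantom(cfg), ph.make_phantom(cfg)
        assert np.array_equal(a.compartment_field, b.compartment_field)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        for k in a.truth_transforms:
            assert np.array_equal(
                a.truth_transforms[k].matrix, b.truth_transforms[k].matrix
            )

    def test_interface_annulus_area(self):
        """Tumor disk r=200 in stroma: interface = annulus 150-250 um."""
        cfg = ph.PhantomConfig(
            seed=1,
            field_size_um=(600.0, 600.0),
            compartment_spec={
                "background": "stroma",
                "disks": [
                    {"compartment": "tumor", "center": (300.0, 300.0), "radius": 200.0}
                ],
                "interface_halfwidth_um": 50.0,
            },
        )
        p = ph.make_phantom(cfg)
        measured = p.interface_mask.sum() * cfg.label_pitch_um**2
        analytic = np.pi * (250.0**2 - 150.0**2)
        assert measured == pytest.approx(analytic, rel=0.02)

    def test_zero_area_compartment_rejected(self):
        cfg = ph.PhantomConfig(
            seed=0,
            field_size_um=(100.0, 100.0),
            compartment_spec={"background": "stroma", "disks": []},
        )  # default programs include "tumor" which has no pixels
        with pytest.raises(ConfigurationError, match="zero area"):
            ph.make_phantom(cfg)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            ph.PhantomConfig(seed=0, mito_fraction=1.2)


class TestCellGeometry:
    def test_cell_spans_4_to_5_contiguous_sections(self):
        """A 20 um cell intersects ceil(20/5)=4 (+/-1) contiguous 5 um sections."""
        cfg = ph.PhantomConfig(
            seed=3,
            field_size_um=(300.0, 300.0),
            n_sections=9,
            section_thickness_um=5.0,
            section_spacing_um=5.0,  # contiguous sectioning
        )
        p = ph.make_phantom(cfg)
        per_cell = []
        membership = {
            s: set(p.cells_in_section(s)["cell_id"]) for s in range(9)
        }
        for cid in p.cells["cell_id"]:
            secs = sorted(s for s in range(9) if cid in membership[s])
            assert secs == list(range(secs[0], secs[-1] + 1)), "must be consecutive"
            per_cell.append(len(secs))
        interior = [
            n
            for n, z in zip(per_cell, p.cells["z_um"])
            if 10.0 <= z <= cfg.block_depth_um - 10.0
        ]
        assert set(interior) <= {4, 5}
        assert interior, "phantom should place interior cells"


class TestChipLayout:
    def test_2x2_grid(self):
        layout = ph.emit_chip_layout(2, 2, pitch_um=1.0, seed=0)
        assert len(layout.barcodes) == 4
        assert all(len(bc) == 25 for bc in layout.barcodes)
        assert set(layout.barcodes.values()) == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_chip_extent_1cm(self):
        """20000 spots at 0.5 um pitch span 1 cm (computed, not emitted)."""
        layout = ph.emit_chip_layout(4, 4, pitch_um=0.5, seed=0)
        n_spots_side = 20000
        assert n_spots_side * layout.pitch_um == pytest.approx(10_000.0)  # um = 1 cm

    def test_min_pairwise_hamming_enforced(self, small_layout):
        """Separation >= 3 so that 1-mismatch correction is unambiguous."""
        bcs = list(small_layout.barcodes)
        arr = np.array([[ord(c) for c in b] for b in bcs], dtype=np.uint8)
        d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        np.fill_diagonal(d, 99)
        assert d.min() >= 3


class TestEmitStereoReads:
    def test_single_clean_read(self):
        cfg = ph.PhantomConfig(
            seed=0,
            field_size_um=(10.0, 10.0),
            compartment_spec={"background": "stroma", "disks": []},
            gene_programs={"stroma": {"G0": 1.0}},
            analyte_maps={"stroma": {100.0: 1.0}},
            phenotypes=(),
            cell_density_per_mm2={},
            mito_fraction=0.0,
            microbe_fraction=0.0,
            barcode_error_rate=0.0,
            mid_lowq_rate=0.0,
        )
        p = ph.make_phantom(cfg)
        layout = ph.emit_chip_layout(1, 1, pitch_um=1.0, seed=0)
        reads = ph.emit_stereo_reads(p, 0, layout, depth=1)
        assert len(reads) == 1
        (seq1, qual1), seq2 = reads.read1[0], reads.read2[0]
        assert seq1[:25] == next(iter(layout.barcodes))
        assert len(seq1) == 31 and all(q == 30 for q in qual1)
        assert seq2 == p.reference.tag("G0")

    def test_truth_table_conservation(self, disk_phantom, small_layout):
        reads = ph.emit_stereo_reads(disk_phantom, 0, small_layout, depth=3)
        assert len(reads.truth) == len(reads) == len(reads.read2)

    def test_mito_fraction_binomial(self, small_layout):
        """With mito fraction 0.01 over 1e5 reads, count within 3 sigma."""
        cfg = ph.PhantomConfig(
            seed=9, field_size_um=(40.0, 40.0), mito_fraction=0.01,
            microbe_fraction=0.0, barcode_error_rate=0.0,
            compartment_spec={
                "background": "stroma",
                "disks": [{"compartment": "tumor", "center": (20.0, 20.0), "radius": 12.0}],
                "interface_halfwidth_um": 5.0,
            },
        )
        p = ph.make_phantom(cfg)
        n = 100_000
        depth = n / small_layout.n_spots
        reads = ph.emit_stereo_reads(p, 0, small_layout, depth=depth)
        n_mito = (reads.truth["category"] == "mito").sum()
        expect = len(reads) * 0.01
        sigma = np.sqrt(len(reads) * 0.01 * 0.99)
        assert abs(n_mito - expect) <= 3 * sigma

    def test_barcode_error_rate(self, small_layout):
        """~5% of CIDs should sit at Hamming distance 1 from their truth."""
        cfg = ph.PhantomConfig(
            seed=4, field_size_um=(40.0, 40.0), barcode_error_rate=0.05,
            mid_lowq_rate=0.0,
            compartment_spec={
                "background": "stroma",
                "disks": [{"compartment": "tumor", "center": (20.0, 20.0), "radius": 12.0}],
                "interface_halfwidth_um": 5.0,
            },
        )
        p = ph.make_phantom(cfg)
        reads = ph.emit_stereo_reads(p, 0, small_layout, depth=25)
        inv = {v: k for k, v in small_layout.barcodes.items()}
        dists = [
            _hamming(seq1[:25], inv[(row.x_index, row.y_index)])
            for (seq1, _), row in zip(reads.read1, reads.truth.itertuples())
        ]
        dists = np.array(dists)
        assert set(dists) <= {0, 1}
        frac = (dists == 1).mean()
        sigma = np.sqrt(0.05 * 0.95 / len(dists))
        assert abs(frac - 0.05) <= 4 * sigma
        errs = reads.truth["cid_errors"].to_numpy()
        assert np.array_equal(dists == 1, errs == 1)


class TestEmitMSI:
    def test_uniform_single_peak(self):
        cfg = ph.PhantomConfig(
            seed=0,
            field_size_um=(100.0, 100.0),
            compartment_spec={"background": "stroma", "disks": []},
            gene_programs={"stroma": {"G0": 1.0}},
            analyte_maps={"stroma": {500.0: 7.0}},
            phenotypes=(),
            cell_density_per_mm2={},
            misalignment={"msi": {"rotation_deg": 0.0, "translation_um": (0.0, 0.0)}},
        )
        p = ph.make_phantom(cfg)
        ds = ph.emit_msi(p, 0, [500.0], pixel_pitch_um=20.0, noise_sd=0.0, seed=0)
        assert all(np.allclose(it, [7.0]) for it in ds.intensities)

    def test_grid_shape_50x50_over_1mm(self, disk_phantom):
        cfg = ph.PhantomConfig(seed=0, field_size_um=(1000.0, 1000.0))
        p = ph.make_phantom(cfg)
        ds = ph.emit_msi(p, 0, [136.076], pixel_pitch_um=20.0, seed=0)
        assert ds.grid_shape == (50, 50)
        assert ds.n_pixels == 2500

    def test_identity_alignment_correlates_with_truth(self):
        cfg = ph.PhantomConfig(
            seed=2,
            field_size_um=(400.0, 400.0),
            misalignment={"msi": {"rotation_deg": 0.0, "translation_um": (0.0, 0.0)}},
        )
        p = ph.make_phantom(cfg)
        ds = ph.emit_msi(p, 0, [1077.361], pixel_pitch_um=20.0, noise_sd=0.0, seed=0)
        from spatialfuse.msi_tools import extract_ion_image

        img = extract_ion_image(ds, 1077.361, 15.0).image
        truth = p.analyte_truth_raster(1077.361, 20.0)
        r = np.corrcoef(img.ravel(), truth.ravel())[0, 1]
        assert r > 0.9

    def test_empty_peak_list_rejected(self, disk_phantom):
        with pytest.raises(ValueError):
            ph.emit_msi(disk_phantom, 0, [], pixel_pitch_um=20.0, seed=0)


class TestEmitSeqIF:
    def _bare_config(self, **kw):
        base = dict(
            seed=0,
            field_size_um=(100.0, 100.0),
            compartment_spec={"background": "stroma", "disks": []},
            gene_programs={"stroma": {"G0": 1.0}},
            analyte_maps={"stroma": {100.0: 1.0}},
            phenotypes=(ph.PhenotypeSpec("immune", {"CD45": 1.0}, ("stroma",)),),
            cell_density_per_mm2={},
            compartment_marker_levels={},
            misalignment={"seqif": {"rotation_deg": 0.0, "translation_um": (0.0, 0.0)}},
        )
        base.update(kw)
        return ph.PhantomConfig(**base)

    def test_no_cells_blank_dapi(self):
        p = ph.make_phantom(self._bare_config())
        names, img = ph.emit_seqif(p, 0, ["DAPI", "CD45"], pixel_pitch_um=1.0, seed=0)
        assert img[names.index("DAPI")].max() == 0.0

    def test_requires_dapi(self, disk_phantom):
        with pytest.raises(ValueError, match="DAPI"):
            ph.emit_seqif(disk_phantom, 0, ["CD45"], pixel_pitch_um=1.0, seed=0)

    def test_100_nuclei_give_100_components(self):
        """Non-overlapping placed nuclei -> 100 connected components."""
        from skimage.measure import label

        p = ph.make_phantom(self._bare_config(field_size_um=(500.0, 500.0)))
        grid = np.arange(10) * 50.0 + 25.0
        gx, gy = np.meshgrid(grid, grid)
        p.cells = pd.DataFrame(
            {
                "cell_id": np.arange(100),
                "phenotype": "immune",
                "x_um": gx.ravel(),
                "y_um": gy.ravel(),
                "z_um": 2.5,
                "diameter_um": 20.0,
                "nucleus_diameter_um": 10.0,
            }
        )
        names, img = ph.emit_seqif(p, 0, ["DAPI", "CD45"], pixel_pitch_um=1.0, seed=0)
        n = label(img[names.index("DAPI")] > 0.5).max()
        assert n == 100

    def test_keratin_only_over_tumor(self, disk_phantom):
        """With only tumor cells expressing keratin, signal stays in tumor."""
        cfg = ph.PhantomConfig(
            seed=7,
            field_size_um=(400.0, 400.0),
            compartment_spec={
                "background": "stroma",
                "disks": [
                    {"compartment": "tumor", "center": (200.0, 200.0), "radius": 140.0}
                ],
                "interface_halfwidth_um": 0.0,
            },
            compartment_marker_levels={},
            misalignment={"seqif": {"rotation_deg": 0.0, "translation_um": (0.0, 0.0)}},
        )
        p = ph.make_phantom(cfg)
        names, img = ph.emit_seqif(
            p, 0, ["DAPI", "Keratin8/18"], pixel_pitch_um=2.0, seed=0
        )
        ker = img[names.index("Keratin8/18")]
        ys, xs = np.nonzero(ker > 0)
        pts = np.column_stack([(xs + 0.5) * 2.0, (ys + 0.5) * 2.0])
        codes = p.compartment_at(pts, with_interface=False)
        dist = np.sqrt((pts[:, 0] - 200.0) ** 2 + (pts[:, 1] - 200.0) ** 2)
        # whole-cell disks may poke over the boundary by a cell radius
        assert ((codes == p.compartment_code("tumor")) | (dist <= 150.0 + 1e-9)).all()
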