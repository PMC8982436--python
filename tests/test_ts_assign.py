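"""Transcription-site calling and spot-to-cell assignment."""

import numpy as np
import pandas as pd
import pytest

from embryoquant.quant import (
    assign_spots_to_cells,
    build_cell_table,
    call_transcription_sites,
    check_conservation,
    quantify_image,
)


def _spot_df(rows):
    return pd.DataFrame(rows, columns=["x", "y", "channel", "intensity",
                                       "cell_label"])


class TestAssignment:
    def test_all_spots_in_one_cell(self, square_grid_labels):
        spots = _spot_df([(4.2, 3.7, "exon", 10.0, 0),
                          (6.1, 5.5, "exon", 10.0, 0)])
        out = assign_spots_to_cells(spots, square_grid_labels)
        assert (out["cell_label"] == 1).all()
        cells = build_cell_table(out, square_grid_labels)
        assert cells.loc[cells["label"] == 1, "mrna_count"].item() == 2
        assert (cells.loc[cells["label"] != 1, "mrna_count"] == 0).all()

    def test_spot_on_zero_pixel_unassigned(self, square_grid_labels):
        lab = square_grid_labels.copy()
        lab[:5, :5] = 0
        spots = _spot_df([(2.0, 2.0, "exon", 10.0, 0)])
        out = assign_spots_to_cells(spots, lab)
        assert (out["cell_label"] == 0).all()
        cells = build_cell_table(out, lab)
        assert cells["mrna_count"].sum() == 0
        assert check_conservation(out, cells)

    def test_out_of_bounds_coordinates_rejected(self, square_grid_labels):
        spots = _spot_df([(99.0, 2.0, "exon", 10.0, 0)])
        with pytest.raises(ValueError):
            assign_spots_to_cells(spots, square_grid_labels)


class TestTSCalling:
    nuclei = np.zeros((30, 30), dtype=bool)
    nuclei[3:8, 3:8] = True  # nucleus patch inside cell 1

    def test_no_intron_spots_means_no_ts(self, square_grid_labels):
        exon = _spot_df([(4.0, 4.0, "exon", 10.0, 1)])
        out, ts, counts = call_transcription_sites(
            exon, exon.iloc[:0], self.nuclei, coloc_radius_px=2.0)
        assert len(counts) == 0
        assert not out["is_ts"].any()

    def test_coincident_pair_flags_exon_spot(self, square_grid_labels):
        exon = _spot_df([(5.0, 5.0, "exon", 60.0, 1),
                         (14.0, 4.0, "exon", 10.0, 2)])
        intron = _spot_df([(5.2, 4.9, "intron", 50.0, 1)])
        out, ts, counts = call_transcription_sites(
            exon, intron, self.nuclei, coloc_radius_px=2.0)
        assert counts.to_dict() == {1: 1}
        assert out["is_ts"].tolist() == [True, False]
        cells = build_cell_table(out, square_grid_labels)
        # the TS-flagged exon spot is excluded from the mature-mRNA count
        assert cells.loc[cells["label"] == 1, "mrna_count"].item() == 0
        assert check_conservation(out, cells)

    def test_intron_spot_outside_nuclei_is_not_ts(self, square_grid_labels):
        exon = _spot_df([(25.0, 25.0, "exon", 10.0, 9)])
        intron = _spot_df([(25.0, 25.0, "intron", 50.0, 9)])
        out, ts, counts = call_transcription_sites(
            exon, intron, self.nuclei, coloc_radius_px=2.0)
        assert len(ts) == 0 and len(counts) == 0
        assert not out["is_ts"].any()

    def test_unmatched_intron_spot_still_counts(self):
        exon = _spot_df([])
        intron = _spot_df([(5.0, 5.0, "intron", 50.0, 1)])
        out, ts, counts = call_transcription_sites(
            exon, intron, self.nuclei, coloc_radius_px=2.0)
        assert counts.to_dict() == {1: 1}

    def test_ts_count_capped_at_four(self):
        intron = _spot_df([(4.0 + 0.3 * i, 4.0, "intron", 50.0, 1)
                           for i in range(6)])
        _, _, counts = call_transcription_sites(
            _spot_df([]), intron, self.nuclei, coloc_radius_px=1.0)
        assert counts.to_dict() == {1: 4}

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            call_transcription_sites(_spot_df([]), _spot_df([]),
                                     self.nuclei, coloc_radius_px=0.0)


class TestEndToEnd:
    def test_noiseless_counts_exact(self, noiseless_embryo):
        """Noise-free, well-separated spots: every cell's mRNA and TS count
        equals the ground truth exactly."""
        e = noiseless_embryo
        cells, spots = quantify_image(
            e["stack"], e["cfg"].psf_sigma_px, labels=e["cellmap"].label_image,
            nuclei_mask=e["nuclei_mask"], cellmap=e["cellmap"])
        merged = cells.merge(e["gt"].cells, on="label")
        assert (merged["mrna_count"] == merged["true_mrna"]).all()
        assert (merged["ts_count"] == merged["true_ts"]).all()
        exon = spots[spots["channel"] == "exon"]
        assert check_conservation(exon, cells)

    def test_conservation_at_default_snr(self, default_embryo):
        e = default_embryo
        cells, spots = quantify_image(
            e["stack"], e["cfg"].psf_sigma_px, labels=e["cellmap"].label_image,
            nuclei_mask=e["nuclei_mask"], cellmap=e["cellmap"])
        exon = spots[spots["channel"] == "exon"]
        assert check_conservation(exon, cells)

    def test_recovery_at_default_snr(self, default_embryo):
        """Realistic SNR: counted mRNA correlates with truth at r >= 0.95 and
        the 0/1/2+ TS class is right for >= 90% of cells."""
        e = default_embryo
        cells, _ = quantify_image(
            e["stack"], e["cfg"].psf_sigma_px, labels=e["cellmap"].label_image,
            nuclei_mask=e["nuclei_mask"], cellmap=e["cellmap"])
        m = cells.merge(e["gt"].cells, on="label")
        r = np.corrcoef(m["mrna_count"], m["true_mrna"])[0, 1]
        assert r >= 0.95
        cls = np.minimum(m["ts_count"].to_numpy(), 2)
        true_cls = np.minimum(m["true_ts"].to_numpy(), 2)
        assert (cls == true_cls).mean() >= 0.90
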