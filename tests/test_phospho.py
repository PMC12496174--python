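"""Phosphosite normalization/filtering, enrichment, motif scan, conservation."""

import numpy as np
import pandas as pd
import pytest

import presynquant as pq


def _site_table(rows):
    """Rows: (position, residue, prob, intensities tuple, variant)."""
    records = []
    for pos, res, prob, intens, variant in rows:
        rec = {
            "protein_id": "PLPPR3",
            "variant": variant,
            "residue": res,
            "position": pos,
            "localization_prob": prob,
        }
        for k, v in enumerate(intens, 1):
            rec[f"intensity_rep{k}"] = v
            rec[f"protein_abundance_rep{k}"] = 2.0
        records.append(rec)
    return pd.DataFrame(records)


class TestNormalize:
    def test_simple_ratio(self):
        table = _site_table([(10, "S", 0.9, (10.0, 10.0, 10.0, 10.0), "ICDm")])
        out = pq.normalize_site_intensities(table)
        assert out["intensity_rep1"].iloc[0] == pytest.approx(5.0)

    def test_missing_stays_missing(self):
        table = _site_table([(10, "S", 0.9, (10.0, np.nan, 10.0, np.nan), "ICDm")])
        out = pq.normalize_site_intensities(table)
        assert np.isnan(out["intensity_rep2"].iloc[0])

    def test_ratio_invariance_under_common_doubling(self):
        table = _site_table([(10, "S", 0.9, (10.0, 12.0, 8.0, 9.0), "ICDm")])
        doubled = table.copy()
        for k in range(1, 5):
            doubled[f"intensity_rep{k}"] *= 2
            doubled[f"protein_abundance_rep{k}"] *= 2
        a = pq.normalize_site_intensities(table)
        b = pq.normalize_site_intensities(doubled)
        cols = [f"intensity_rep{k}" for k in range(1, 5)]
        pd.testing.assert_frame_equal(a[cols], b[cols])

    def test_zero_abundance_rejected(self):
        table = _site_table([(10, "S", 0.9, (10.0, 10.0, 10.0, 10.0), "ICDm")])
        table["protein_abundance_rep1"] = 0.0
        with pytest.raises(ValueError):
            pq.normalize_site_intensities(table)


class TestHighConfidenceFilter:
    def test_three_of_four_kept(self):
        table = _site_table([(351, "S", 0.8, (1.0, 1.0, 1.0, np.nan), "ICDm")])
        assert len(pq.high_confidence_filter(table)) == 1

    def test_boundary_prob_dropped(self):
        # exactly 0.75 fails the strict > rule even at 4/4 replicates
        table = _site_table([(351, "S", 0.75, (1.0, 1.0, 1.0, 1.0), "ICDm")])
        assert len(pq.high_confidence_filter(table)) == 0

    def test_two_of_four_dropped(self):
        table = _site_table([(351, "S", 0.9, (1.0, 1.0, np.nan, np.nan), "ICDm")])
        assert len(pq.high_confidence_filter(table)) == 0

    def test_variant_union_and_flags(self):
        table = _site_table(
            [
                (351, "S", 0.9, (1.0, 1.0, 1.0, 1.0), "ICDm"),
                (351, "S", 0.9, (1.0, 1.0, 1.0, 1.0), "ICDc"),
                (380, "T", 0.9, (1.0, 1.0, 1.0, 1.0), "ICDm"),
                (400, "S", 0.9, (1.0, 1.0, np.nan, np.nan), "ICDc"),
            ]
        )
        kept = pq.high_confidence_filter(table).set_index("position")
        assert kept.loc[351, "variant_class"] == "both"
        assert kept.loc[380, "variant_class"] == "unique_to_ICDm"
        assert 400 not in kept.index

    def test_monotone_in_thresholds(self):
        table, _ = pq.generate_phosphosite_table(pq.SimulationConfig(seed=13), n_sites=100)
        strict = set(pq.high_confidence_filter(table, 3, 4, 0.75)["position"])
        looser_prob = set(pq.high_confidence_filter(table, 3, 4, 0.5)["position"])
        looser_reps = set(pq.high_confidence_filter(table, 2, 4, 0.75)["position"])
        assert strict <= looser_prob
        assert strict <= looser_reps

    def test_matches_bruteforce_oracle(self):
        table, truth = pq.generate_phosphosite_table(pq.SimulationConfig(seed=21), n_sites=200)
        normalized = pq.normalize_site_intensities(table)
        kept = set(pq.high_confidence_filter(normalized)["position"])
        # independent row-by-row re-implementation
        expected = set()
        for _, row in table.iterrows():
            present = sum(
                not np.isnan(row[f"intensity_rep{k}"]) for k in range(1, 5)
            )
            if present >= 3 and row["localization_prob"] > 0.75:
                expected.add(row["position"])
        assert kept == expected
        assert kept == set(truth.site_truth.loc[truth.site_truth["truth_pass"], "position"])


class TestEnrichmentFilter:
    @staticmethod
    def _records(rows):
        """Rows: (protein, group, values)."""
        return pd.DataFrame(
            [
                {
                    "protein_id": p,
                    "group": g,
                    **{f"log2_rep{k}": v for k, v in enumerate(vals, 1)},
                }
                for p, g, vals in rows
            ]
        )

    def test_simple_enrichment(self):
        records = self._records(
            [("BASP1", "phospho", (10.0, 10.0)), ("BASP1", "control", (8.0, 8.0))]
        )
        result = pq.enrichment_filter(records)
        assert result["enriched_phospho"] == ["BASP1"]
        assert result["enriched_control"] == []

    def test_equal_groups_not_enriched(self):
        records = self._records(
            [("X", "phospho", (9.0, 9.0)), ("X", "control", (9.0, 9.0))]
        )
        result = pq.enrichment_filter(records)
        assert result["enriched_phospho"] == [] and result["enriched_control"] == []

    def test_directions_disjoint_and_oracle(self, rng):
        rows = []
        for i in range(40):
            rows.append((f"P{i:02d}", "phospho", tuple(rng.normal(10, 2, 3))))
            rows.append((f"P{i:02d}", "control", tuple(rng.normal(10, 2, 3))))
        records = self._records(rows)
        result = pq.enrichment_filter(records)
        up = set(result["enriched_phospho"])
        down = set(result["enriched_control"])
        assert not up & down
        # brute-force recomputation
        for protein in records["protein_id"].unique():
            sub = records[records["protein_id"] == protein]
            vals = {
                g: sub[sub["group"] == g][[f"log2_rep{k}" for k in (1, 2, 3)]].to_numpy().ravel()
                for g in ("control", "phospho")
            }
            fc = vals["phospho"].mean() - vals["control"].mean()
            assert (protein in up) == (fc >= 2.0)
            assert (protein in down) == (fc <= -2.0)

    def test_min_valid_exclusion(self):
        records = self._records(
            [("Y", "phospho", (np.nan, np.nan)), ("Y", "control", (np.nan, 5.0))]
        )
        result = pq.enrichment_filter(records)
        assert result["excluded"] == ["Y"]


class TestPkaMotifScan:
    def test_printed_peptide_single_hit(self):
        hits = pq.pka_motif_scan("LKRASVDVDLLA")
        assert len(hits) == 1
        assert hits[0].position == 5
        assert hits[0].residue == "S"

    def test_no_basic_context_no_hits(self):
        assert pq.pka_motif_scan("AAAASAAAA") == []

    def test_canonical_rras(self):
        hits = pq.pka_motif_scan("RRAS")
        assert [h.position for h in hits] == [4]

    def test_motif_is_directional(self):
        forward = pq.pka_motif_scan("LKRASVDVDLLA")
        reverse = pq.pka_motif_scan("LKRASVDVDLLA"[::-1])
        assert [h.position for h in forward] != [h.position for h in reverse]

    def test_invalid_letters_rejected(self):
        with pytest.raises(ValueError):
            pq.pka_motif_scan("RRXS1")

    def test_region_restriction(self):
        seq = "RRASAAAARRAS"
        assert len(pq.pka_motif_scan(seq)) == 2
        assert len(pq.pka_motif_scan(seq, region=(1, 6))) == 1
        with pytest.raises(ValueError):
            pq.pka_motif_scan(seq, region=(0, 99))


class TestConservation:
    @staticmethod
    def _write_alignment(tmp_path, seqs):
        path = tmp_path / "aln.fasta"
        with open(path, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        return path

    def test_fully_conserved(self, tmp_path):
        seqs = {f"sp{i}": "AASKK" for i in range(6)}
        seqs["mouse"] = "AASKK"
        path = self._write_alignment(tmp_path, seqs)
        rec = pq.conservation_ratio(path, "mouse", 3)
        assert rec.reference_residue == "S"
        assert rec.ratio == f"{len(seqs)}/{len(seqs)}"

    def test_mixed_column_with_gap(self, tmp_path):
        # reference S; column S,S,S,T,E,-: 3 conserved, T conservative, gap not
        path = self._write_alignment(
            tmp_path,
            {
                "mouse": "AASKK",
                "human": "AASKK",
                "fish": "AASKK",
                "frog": "AATKK",
                "chick": "AAEKK",
                "monkey": "AA-KK",
            },
        )
        rec = pq.conservation_ratio(path, "mouse", 3)
        assert rec.conserved == 3
        assert rec.total == 6
        assert rec.conservative == 1

    def test_gapped_reference_coordinates(self, tmp_path):
        # reference has a gap: ungapped position 3 maps to column 4
        path = self._write_alignment(
            tmp_path, {"mouse": "AA-SK", "human": "AAQSK", "fish": "AAQTK"}
        )
        rec = pq.conservation_ratio(path, "mouse", 3)
        assert rec.reference_residue == "S"
        assert rec.conserved == 2

    def test_position_beyond_reference_rejected(self, tmp_path):
        path = self._write_alignment(tmp_path, {"mouse": "AAS", "human": "AAT"})
        with pytest.raises(ValueError):
            pq.conservation_ratio(path, "mouse", 9)

    def test_matches_column_scan_oracle(self, tmp_path, rng):
        names = [f"s{i}" for i in range(6)]
        seqs = {
            n: "".join(rng.choice(list("ASTDE-"), size=12)) for n in names
        }
        seqs["ref"] = "".join(rng.choice(list("ASTDE"), size=12))  # ungapped reference
        path = self._write_alignment(tmp_path, seqs)
        for position in (1, 5, 12):
            rec = pq.conservation_ratio(path, "ref", position)
            column = [seqs[n][position - 1] for n in list(seqs)]
            expected = sum(aa == seqs["ref"][position - 1] for aa in column)
            assert rec.conserved == expected
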