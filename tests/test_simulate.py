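"""Ground-truth bookkeeping and statistical structure of the generator."""

import filecmp

import numpy as np
import pytest

from myrmitox.sequence import reverse_complement, translate
from myrmitox.simulate import (
    ConfigError,
    SimConfig,
    generate_counts,
    generate_dataset,
    generate_psm_table,
)

SMALL = dict(n_background=10, n_reads=200)


class TestConfig:
    def test_invalid_enrichment_names_field(self):
        with pytest.raises(ConfigError, match="enrichment_factor"):
            SimConfig(enrichment_factor=0)

    def test_negative_count_names_field(self):
        with pytest.raises(ConfigError, match="n_background"):
            SimConfig(n_background=-1)

    def test_mature_range_bounds(self):
        with pytest.raises(ConfigError, match="mature_len_range"):
            SimConfig(mature_len_range=(10, 56))


class TestDeterminismAndManifest:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=5, **SMALL)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(cfg).write(d1)
        generate_dataset(cfg).write(d2)
        names = [p.name for p in d1.iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert sorted(match) == sorted(names) and not mismatch and not errors

    def test_all_counts_zero_gives_empty_outputs(self):
        cfg = SimConfig(
            n_toxins_per_family={}, n_background=0, n_egf=0, n_reads=0
        )
        ds = generate_dataset(cfg)
        assert ds.transcripts == [] and ds.manifest.entries == {}
        assert len(ds.count_table) == 0 and len(ds.psm_table) == 0
        assert ds.barcode_reads == []

    def test_family_tally_matches_config(self):
        cfg = SimConfig(
            n_toxins_per_family={"VSP": 5, "CAP": 3},
            n_egf=2,
            n_background=5,
            n_reads=0,
        )
        ds = generate_dataset(cfg)
        assert ds.manifest.family_tally() == {"VSP": 5, "CAP": 3, "EGF": 2}

    def test_fasta_and_manifest_agree(self):
        ds = generate_dataset(SimConfig(seed=6, **SMALL))
        assert {r.id for r in ds.transcripts} == set(ds.manifest.entries)

    def test_planted_orf_translates_to_stored_protein(self):
        ds = generate_dataset(SimConfig(seed=8, **SMALL))
        seqs = {r.id: r.seq for r in ds.transcripts}
        for tid, e in ds.manifest.entries.items():
            if not e.is_toxin:
                continue
            span = seqs[tid][e.start - 1 : e.end]
            if e.strand == "-":
                span = reverse_complement(span)
            assert translate(span) == e.protein
            assert 1 <= e.start <= e.end <= len(seqs[tid])

    def test_manifest_round_trips_json(self, tmp_path):
        ds = generate_dataset(SimConfig(seed=9, **SMALL))
        path = tmp_path / "manifest.json"
        ds.manifest.to_json(path)
        from myrmitox.simulate import TruthManifest

        back = TruthManifest.from_json(path)
        assert back == ds.manifest


class TestCounts:
    def _flat_manifest(self, n, base_mean=100.0):
        from myrmitox.simulate import ManifestEntry, TruthManifest

        m = TruthManifest(species_tag="Mrub", barcode_species="Myrmica rubra")
        for i in range(n):
            m.entries[f"T{i:05d}"] = ManifestEntry(
                transcript_id=f"T{i:05d}",
                length=500,
                is_toxin=True,
                family="VSP",
                gland_enriched=True,
                gland_only=False,
                base_mean=base_mean,
            )
        return m

    def test_unit_enrichment_equalizes_means(self):
        cfg = SimConfig(enrichment_factor=1.0, nb_dispersion=10.0)
        manifest = self._flat_manifest(2000)
        counts = generate_counts(manifest, cfg, rng=np.random.default_rng(50))
        gland = counts[counts["sample_id"].str.startswith("gland")]["count"]
        body = counts[counts["sample_id"].str.startswith("body")]["count"]
        # moment check: NB(mu=100, size=10) has var = mu + mu^2/size = 1100
        se = np.sqrt(1100.0 / len(gland)) + np.sqrt(1100.0 / len(body))
        assert abs(gland.mean() - body.mean()) < 3 * se

    def test_poisson_limit_variance_equals_mean(self):
        cfg = SimConfig(nb_dispersion=float("inf"), enrichment_factor=1.0)
        manifest = self._flat_manifest(3000)
        counts = generate_counts(manifest, cfg, rng=np.random.default_rng(51))
        x = counts["count"].to_numpy()
        assert x.var() / x.mean() == pytest.approx(1.0, abs=0.1)

    def test_gland_only_zero_body_counts(self):
        from myrmitox.simulate import ManifestEntry, TruthManifest

        m = TruthManifest(species_tag="Mrub", barcode_species="Myrmica rubra")
        m.entries["T0"] = ManifestEntry(
            transcript_id="T0",
            length=400,
            is_toxin=True,
            family="VSP",
            gland_enriched=True,
            gland_only=True,
            base_mean=50.0,
        )
        counts = generate_counts(m, SimConfig(), rng=np.random.default_rng(52))
        body = counts[counts["sample_id"].str.startswith("body")]
        assert (body["count"] == 0).all()


class TestPsms:
    def test_verified_toxins_get_two_distinct_peptides(self):
        ds = generate_dataset(SimConfig(seed=10, **SMALL))
        targets = ds.psm_table[~ds.psm_table["is_decoy"]]
        for tid, e in ds.manifest.entries.items():
            if e.is_toxin and e.proteome_verified:
                rows = targets[targets["orf_id"] == e.orf_id]
                assert rows["peptide"].nunique() >= 2
                floor = 60.0 - 2 * 15.0
                assert (rows["score"].nlargest(2) > floor).all()

    def test_decoy_tail_above_target_mean_is_small(self):
        from myrmitox.simulate import ManifestEntry, TruthManifest

        m = TruthManifest(species_tag="Mrub", barcode_species="Myrmica rubra")
        rng = np.random.default_rng(53)
        prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        for i in range(500):
            m.entries[f"T{i:04d}"] = ManifestEntry(
                transcript_id=f"T{i:04d}",
                length=500,
                is_toxin=True,
                family="VSP",
                protein=prot,
                proteome_verified=True,
                orf_id=f"T{i:04d}|+0|1-360",
                base_mean=10.0,
            )
        cfg = SimConfig(n_decoy_psms=1000)
        psms = generate_psm_table(m, cfg, rng=np.random.default_rng(54))
        decoys = psms[psms["is_decoy"]]
        assert len(decoys) == 1000
        # P(N(15, 8) > 60) is ~ 1e-8; allow the stated 5% margin
        assert (decoys["score"] > 60.0).mean() < 0.05

    def test_seed_determinism(self):
        cfg = SimConfig(seed=12, **SMALL)
        t1 = generate_dataset(cfg).psm_table
        t2 = generate_dataset(cfg).psm_table
        assert t1.equals(t2)
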