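"""Ground-truth generation, recovery guarantees and fixture bundles."""

import numpy as np
import pytest

import ldrkit as lk
from ldrkit.synthetic_data import (
    PLANTED_TERM,
    SimConfig,
    generate,
    to_pdb_text,
    write_fixture_bundle,
)


def noiseless_config(**kw):
    base = dict(n_proteins=10, p_miss_given_disordered=1.0,
                p_miss_given_structured=0.0, trim_probability=0.0, seed=7)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a = generate(SimConfig(n_proteins=4, seed=9))
        b = generate(SimConfig(n_proteins=4, seed=9))
        assert {p: g.states for p, g in a.ground_truths.items()} == \
               {p: g.states for p, g in b.ground_truths.items()}
        assert a.sequences == b.sequences
        assert [o.states for o in a.observations] == [o.states for o in b.observations]
        assert a.quality.equals(b.quality)
        assert a.annotations == b.annotations

    def test_per_protein_substreams_stable_under_n_proteins(self):
        small = generate(SimConfig(n_proteins=3, seed=9))
        large = generate(SimConfig(n_proteins=6, seed=9))
        for pid in small.ground_truths:
            assert small.ground_truths[pid].states == \
                large.ground_truths[pid].states
            assert small.sequences[pid] == large.sequences[pid]

    def test_manifest_hash_tracks_config(self, tmp_path):
        a = SimConfig(n_proteins=3, seed=1)
        b = SimConfig(n_proteins=3, seed=2)
        assert a.config_hash() == SimConfig(n_proteins=3, seed=1).config_hash()
        assert a.config_hash() != b.config_hash()
        manifest = write_fixture_bundle(generate(a), tmp_path / "x")
        assert manifest["config_hash"] == a.config_hash()
        assert manifest["seed"] == 1


class TestNoiselessRecovery:
    def test_consensus_equals_ground_truth(self):
        ds = generate(noiseless_config())
        stacks = lk.build_stacks(ds.observations, ds.segments, ds.sequences)
        for pid, stack in stacks.items():
            gt = ds.ground_truths[pid]
            assert lk.majority_consensus(stack).states == gt.states
            assert lk.zero_consensus(stack).states == gt.states

    def test_regions_equal_ground_truth_regions(self):
        ds = generate(noiseless_config())
        stacks = lk.build_stacks(ds.observations, ds.segments, ds.sequences)
        for pid, stack in stacks.items():
            got = [(r.start, r.end, r.region_class)
                   for r in lk.extract_regions(lk.majority_consensus(stack))]
            expect = [(s, e, c) for s, e, c in ds.ground_truths[pid].regions
                      if c in ("LDR", "SDR")]
            assert got == expect


class TestNoisyRecovery:
    def test_majority_error_rate_bounded_with_many_chains(self):
        """25 chains at miss probabilities 0.8/0.2 keep the per-position
        majority error under 1%."""
        ds = generate(SimConfig(n_proteins=10, n_chains_range=(25, 25),
                                p_miss_given_disordered=0.8,
                                p_miss_given_structured=0.2, seed=13))
        stacks = lk.build_stacks(ds.observations, ds.segments, ds.sequences)
        errors = total = 0
        for pid, stack in stacks.items():
            maj = lk.majority_consensus(stack).states
            truth = ds.ground_truths[pid].states
            for m, t in zip(maj, truth):
                if t == "U":
                    continue
                total += 1
                errors += (m != t)
        assert total > 1000
        assert errors / total < 0.01

    def test_zero_regions_contained_in_majority_regions(self):
        # few chains so that all-chains-missing runs actually occur
        ds = generate(SimConfig(n_chains_range=(4, 6), seed=29))
        stacks = lk.build_stacks(ds.observations, ds.segments, ds.sequences)
        n_zero = 0
        for stack in stacks.values():
            maj_regions = lk.extract_regions(lk.majority_consensus(stack))
            zero_regions = lk.extract_regions(lk.zero_consensus(stack))
            spans = [(r.start, r.end) for r in maj_regions]
            for z in zero_regions:
                n_zero += 1
                assert any(a <= z.start and z.end <= b for a, b in spans)
        assert n_zero > 0


class TestArchitectures:
    def test_explicit_architecture_is_respected(self):
        arch = ((("U", 20), ("S", 50), ("D", 40), ("S", 50)),)
        ds = generate(SimConfig(n_proteins=1, architectures=arch, seed=3))
        gt = next(iter(ds.ground_truths.values()))
        assert gt.states == "U" * 20 + "S" * 50 + "D" * 40 + "S" * 50
        assert gt.true_ldrs() == [(71, 110)]

    def test_uncrystallized_only_architecture_rejected(self):
        with pytest.raises(ValueError):
            generate(SimConfig(n_proteins=1, architectures=((("U", 30),),),
                               seed=0))

    def test_ldr_free_proteins_generated_when_requested(self):
        ds = generate(SimConfig(n_proteins=40, p_ldr_protein=0.2,
                                n_chains_range=(3, 5), seed=31))
        with_ldr = sum(bool(g.true_ldrs()) for g in ds.ground_truths.values())
        assert 0 < with_ldr < 20

    def test_disordered_sequence_composition_is_biased(self):
        ds = generate(SimConfig(n_proteins=30, seed=37))
        dis, bg = [], []
        for pid, gt in ds.ground_truths.items():
            seq = ds.sequences[pid]
            for aa, state in zip(seq, gt.states):
                (dis if state == "D" else bg).append(aa)
        dis_p = dis.count("P") / len(dis)
        bg_p = bg.count("P") / len(bg)
        assert dis_p > bg_p  # proline enriched in disorder
        dis_w = dis.count("W") / len(dis)
        bg_w = bg.count("W") / len(bg)
        assert dis_w < bg_w  # tryptophan depleted


class TestFixtureBundle:
    def test_bundle_round_trips_through_ingest(self, tmp_path, small_dataset):
        from ldrkit.ingest import read_mapping_tsv, read_observations_tsv

        ds = small_dataset
        write_fixture_bundle(ds, tmp_path)
        obs = read_observations_tsv(tmp_path / "observations.tsv")
        assert obs == ds.observations
        segs = read_mapping_tsv(tmp_path / "mapping.tsv")
        assert segs == ds.segments
        # per-structure PDB files reproduce the in-memory observations
        for o in ds.observations[:5]:
            text = (tmp_path / "structures" / f"{o.structure_id}.pdb").read_text()
            (parsed,) = lk.parse_pdb_missing(text)
            assert parsed.states == o.states
            assert parsed.structure_id == o.structure_id

    def test_bundle_fasta_matches_sequences(self, tmp_path, small_dataset):
        from Bio import SeqIO

        write_fixture_bundle(small_dataset, tmp_path)
        seqs = {rec.id: str(rec.seq)
                for rec in SeqIO.parse(tmp_path / "sequences.fasta", "fasta")}
        assert seqs == small_dataset.sequences

    def test_bundle_obo_gaf_satisfy_enrichment_preconditions(
            self, tmp_path, small_dataset):
        from ldrkit.enrichment import enrich, load_gaf, load_ontology

        write_fixture_bundle(small_dataset, tmp_path)
        ont = load_ontology((tmp_path / "ontology.obo").read_text())
        ann = load_gaf((tmp_path / "annotations.gaf").read_text())
        background = list(small_dataset.ground_truths)
        target = small_dataset.ldr_protein_ids() or background[:2]
        df = enrich(target, background, ann, ont)
        assert len(df) > 0
        assert (df.level <= 4).all()


def test_planted_enrichment_scenario_detected():
    """LDR proteins as a minority class carrying a planted GO term must be
    flagged enriched after Bonferroni correction."""
    from ldrkit.enrichment import enrich, load_ontology

    ds = generate(SimConfig(n_proteins=150, p_ldr_protein=0.25,
                            n_chains_range=(3, 8), seed=5))
    targets = ds.ldr_protein_ids()
    assert 10 < len(targets) < 100
    ont = load_ontology(ds.ontology_obo)
    df = enrich(targets, list(ds.ground_truths), ds.annotations, ont)
    row = df[df.term == PLANTED_TERM].iloc[0]
    assert bool(row.enriched)
    assert row.p_bonferroni < 0.05


def test_pdb_text_is_column_aligned():
    text = to_pdb_text("1ABC", [("A", "MKV", "MOO")], release_year=2005)
    atom_lines = [l for l in text.splitlines() if l.startswith("ATOM")]
    assert all(len(l) >= 66 for l in atom_lines)
    for l in atom_lines:
        assert l[21] == "A"
        int(l[22:26])  # resSeq parses
        float(l[30:38])  # x coordinate parses
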