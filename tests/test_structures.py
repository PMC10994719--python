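"""Template selection, chain scoring, and pLDDT trimming."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from xlinkval.fixtures import make_helix_chain, random_sequence
from xlinkval.io import Chain, ProteinRecord, Residue, RunConfig, StructureModel
from xlinkval.structures import (
    chain_sequence,
    find_complex_structures,
    map_link_residue,
    score_chain,
    select_structures,
    trim_by_plddt,
)


def helix_model(seq, structure_id="s1", source="experimental", resolution=2.0,
                chain_ids=("A",), bfactors=None):
    chains = [
        make_helix_chain(len(seq), seq, cid, origin=(i * 20.0, 0, 0),
                         bfactors=bfactors)
        for i, cid in enumerate(chain_ids)
    ]
    return StructureModel(structure_id, source, resolution, chains)


@pytest.fixture(scope="module")
def protein():
    rng = np.random.default_rng(42)
    return ProteinRecord("PROT1", random_sequence(rng, 60))


class TestChainSequence:
    def test_poly_alanine_helix(self):
        model = helix_model("A" * 20)
        seq, omap = chain_sequence(model, model.chains[0])
        assert seq == "A" * 20
        assert omap[1] == (1, "") and omap[20] == (20, "")

    def test_auth_numbering_gap_preserved_without_gap_characters(self):
        model = helix_model("A" * 16)
        chain = model.chains[0]
        renumbered = []
        for k, res in enumerate(chain.residues):
            num = k + 1 if k < 10 else k + 5  # 1-10 then 15-20
            renumbered.append(dataclasses.replace(res, auth_number=num))
        chain2 = Chain("A", renumbered)
        seq, omap = chain_sequence(model, chain2)
        assert len(seq) == 16
        assert omap[10] == (10, "")
        assert omap[11] == (15, "")

    def test_selenomethionine_equivalence_option(self):
        model = helix_model("AMA")
        chain = model.chains[0]
        residues = [
            dataclasses.replace(r, name="MSE") if r.name == "MET" else r
            for r in chain.residues
        ]
        chain_mse = Chain("A", residues)
        seq_on, _ = chain_sequence(model, chain_mse, mse_as_met=True)
        seq_off, _ = chain_sequence(model, chain_mse, mse_as_met=False)
        assert seq_on == "AMA"
        assert seq_off == "AXA"


class TestScoreChain:
    def test_exact_copy_has_full_identity_and_coverage(self, protein):
        model = helix_model(protein.sequence)
        cm = score_chain(protein, model, model.chains[0])
        assert cm.identity == 1.0
        assert cm.coverage == 1.0
        assert cm.residue_map[1] == (1, "") and cm.residue_map[60] == (60, "")

    def test_half_length_chain_has_half_coverage(self, protein):
        model = helix_model(protein.sequence[:30])
        cm = score_chain(protein, model, model.chains[0])
        assert cm.identity == 1.0
        assert cm.coverage == pytest.approx(0.5)

    def test_point_mutant_identity_tracks_mutation_rate(self, protein):
        rng = np.random.default_rng(1)
        seq = list(protein.sequence)
        mutated_idx = rng.choice(60, size=12, replace=False)  # 20% mutated
        for i in mutated_idx:
            choices = [c for c in "ACDEFGHIKLMNPQRSTVWY" if c != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]
        model = helix_model("".join(seq))
        cm = score_chain(protein, model, model.chains[0])
        assert cm.identity == pytest.approx(0.80, abs=0.05)

    def test_residue_map_is_injective(self, protein):
        model = helix_model(protein.sequence)
        cm = score_chain(protein, model, model.chains[0])
        values = list(cm.residue_map.values())
        assert len(values) == len(set(values))


class TestSelectStructures:
    def test_predicted_model_excluded_when_experimental_passes(self, protein, config):
        experimental = helix_model(protein.sequence, "exp1", resolution=3.0)
        predicted = helix_model(protein.sequence, "mod1", source="predicted",
                                resolution=None, bfactors=[90.0] * 60)
        cands = select_structures(protein, [predicted, experimental], config)
        assert [c.structure.structure_id for c in cands] == ["exp1"]

    def test_predicted_model_used_as_fallback(self, protein, config):
        predicted = helix_model(protein.sequence, "mod1", source="predicted",
                                resolution=None, bfactors=[90.0] * 60)
        cands = select_structures(protein, [predicted], config)
        assert [c.structure.structure_id for c in cands] == ["mod1"]

    def test_resolution_above_cutoff_rejected(self, protein, config):
        bad = helix_model(protein.sequence, "bad1", resolution=4.5)
        assert select_structures(protein, [bad], config) == []

    def test_ranking_prefers_higher_identity(self, protein, config):
        exact = helix_model(protein.sequence, "ex1")
        seq = list(protein.sequence)
        for i in (5, 15, 25):  # 3 mutations: identity 0.95
            seq[i] = "A" if seq[i] != "A" else "C"
        mutant = helix_model("".join(seq), "mu1")
        cands = select_structures(protein, [mutant, exact], config)
        assert [c.structure.structure_id for c in cands] == ["ex1", "mu1"]

    def test_strict_cutoffs_keep_only_exact_full_length_matches(self, protein):
        cfg = RunConfig(identity_cutoff=1.0, coverage_cutoff=1.0)
        exact = helix_model(protein.sequence, "ex1")
        partial = helix_model(protein.sequence[:40], "pa1")
        cands = select_structures(protein, [exact, partial], cfg)
        assert [c.structure.structure_id for c in cands] == ["ex1"]

    def test_empty_library_gives_empty_list(self, protein, config):
        assert select_structures(protein, [], config) == []

    def test_all_returned_candidates_satisfy_cutoffs(self, protein, config):
        library = [
            helix_model(protein.sequence, "ex1", resolution=2.0),
            helix_model(protein.sequence[:35], "pa1", resolution=1.5),
        ]
        for cand in select_structures(protein, library, config):
            for maps in cand.chain_maps.values():
                for cm in maps:
                    assert cm.identity >= config.identity_cutoff
                    assert cm.coverage >= config.coverage_cutoff


class TestFindComplexStructures:
    def test_homodimer_found_for_homo_query(self, protein, config):
        dimer = helix_model(protein.sequence, "dim1", chain_ids=("A", "B"))
        cands = find_complex_structures(protein, protein, [dimer], config)
        assert len(cands) == 1
        assert len(cands[0].chain_maps[protein.accession]) == 2

    def test_monomer_rejected_for_homo_query(self, protein, config):
        mono = helix_model(protein.sequence, "mono1")
        assert find_complex_structures(protein, protein, [mono], config) == []

    def test_multimer_with_many_chains_returned(self, protein, config):
        heptamer = helix_model(protein.sequence, "hept1",
                               chain_ids=tuple("ABCDEFG"))
        cands = find_complex_structures(protein, protein, [heptamer], config)
        assert len(cands[0].chain_maps[protein.accession]) == 7

    def test_hetero_query_requires_both_proteins(self, protein, config):
        rng = np.random.default_rng(77)
        other = ProteinRecord("PROT2", random_sequence(rng, 60))
        only_a = helix_model(protein.sequence, "sa1", chain_ids=("A",))
        both = StructureModel(
            "sab1", "experimental", 2.0,
            [make_helix_chain(60, protein.sequence, "A"),
             make_helix_chain(60, other.sequence, "B", origin=(25, 0, 0))],
        )
        cands = find_complex_structures(protein, other, [only_a, both], config)
        assert [c.structure.structure_id for c in cands] == ["sab1"]

    def test_predicted_models_never_complex_templates(self, protein, config):
        fake_dimer = helix_model(protein.sequence, "md1", source="predicted",
                                 resolution=None, chain_ids=("A", "B"),
                                 bfactors=[90.0] * 60)
        assert find_complex_structures(protein, protein, [fake_dimer], config) == []


class TestTrimByPlddt:
    def make_predicted(self, n=100, low_first=0, low_value=60.0):
        b = [low_value] * low_first + [90.0] * (n - low_first)
        return helix_model("A" * n, "mod1", source="predicted",
                           resolution=None, bfactors=b)

    def test_uniformly_confident_model_unchanged(self):
        model = self.make_predicted()
        trimmed = trim_by_plddt(model, 70.0)
        assert len(trimmed.chains[0].residues) == 100

    def test_low_confidence_segment_removed(self):
        model = self.make_predicted(low_first=10)
        trimmed = trim_by_plddt(model, 70.0)
        assert len(trimmed.chains[0].residues) == 90
        assert trimmed.chains[0].residues[0].auth_number == 11

    def test_cutoff_zero_is_identity(self):
        model = self.make_predicted(low_first=10)
        trimmed = trim_by_plddt(model, 0.0)
        assert len(trimmed.chains[0].residues) == 100

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(4)
        b = list(rng.uniform(40, 100, size=50))
        model = helix_model("A" * 50, "mod1", source="predicted",
                            resolution=None, bfactors=b)
        sizes = [
            sum(len(c.residues) for c in trim_by_plddt(model, cut).chains)
            for cut in (0, 50, 70, 90, 101)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_experimental_structure_rejected(self):
        with pytest.raises(ValueError):
            trim_by_plddt(helix_model("A" * 10), 70.0)


class TestMapLinkResidue:
    def test_aligned_position_maps_to_auth_residue(self, protein):
        model = helix_model(protein.sequence)
        cm = score_chain(protein, model, model.chains[0])
        assert map_link_residue(10, cm, len(protein)) == (10, "")

    def test_unobserved_position_unmapped(self, protein):
        model = helix_model(protein.sequence[:30])
        cm = score_chain(protein, model, model.chains[0])
        assert map_link_residue(45, cm, len(protein)) is None

    def test_position_beyond_protein_is_error(self, protein):
        model = helix_model(protein.sequence)
        cm = score_chain(protein, model, model.chains[0])
        with pytest.raises(ValueError):
            map_link_residue(61, cm, len(protein))
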