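"""Family clustering, reference numbering and validity filtering."""

import itertools

import numpy as np
import pytest

from apoholo.config import RunConfig
from apoholo.curation import (Family, build_reference_numbering,
                              cluster_families, curate_cohort, validate_apo,
                              validate_holo)
from apoholo.binding_site import unify_sites
from apoholo.structure import Atom, HetRecord, StructureRecord
from apoholo.synthetic import DecoyHet, FamilyFixtureSpec, make_family, make_ideal_chain

from conftest import load_fixture_structures


def chain(seq, pdb_id="0000", resolution=1.5, role="apo", **kw):
    s = make_ideal_chain(seq, pdb_id=pdb_id, resolution=resolution, role=role, **kw)
    return s


class TestClustering:
    def test_identical_sequences_share_a_family(self):
        fams = cluster_families([chain("ACDEFGHIK", "1aaa"),
                                 chain("ACDEFGHIK", "1bbb")])
        assert len(fams) == 1
        assert len(fams[0].members) == 2

    def test_core_substitution_separates_families(self):
        fams = cluster_families([chain("ACDEFGHIK", "1aaa"),
                                 chain("ACDEWGHIK", "1bbb")])
        assert len(fams) == 2

    def test_terminal_extension_merges_only_when_enabled(self):
        a = chain("ACDEFGHIK", "1aaa")
        b = chain("ACDEFGHIKLMN", "1bbb")  # + 3 C-terminal residues
        assert len(cluster_families([a, b])) == 2
        merged = cluster_families([a, b], merge_terminal_extensions=True)
        assert len(merged) == 1
        assert len(merged[0].members) == 2

    def test_internal_insertion_never_merges(self):
        a = chain("ACDEFGHIK", "1aaa")
        b = chain("ACDEWWFGHIK", "1bbb")
        assert len(cluster_families([a, b], merge_terminal_extensions=True)) == 2

    def test_empty_input(self):
        assert cluster_families([]) == []


class TestReferenceNumbering:
    def test_pure_offset_mapping(self):
        ref = chain("ACDEFGHIKLMNPQRSTVWY", "1ref", resolution=1.2)
        mem = chain("ACDEFGHIKLMNPQRSTVWY", "2mem", resolution=2.0, start_seq=70)
        fam = Family("F1", [ref, mem])
        build_reference_numbering(fam)
        assert fam.reference_id == "1ref"
        assert not fam.decisions
        for res in mem.chains["A"]:
            assert res.ref_index == res.auth_seq - 69

    def test_missing_residues_map_around_the_gap(self):
        ref = chain("ACDEFGHIKLMNPQRSTVWY", "1ref", resolution=1.2)
        mem = chain("ACDEFGHIKLMNPQRSTVWY", "2mem", resolution=2.0)
        del mem.chains["A"][9:12]  # unresolved stretch
        fam = Family("F1", [ref, mem])
        build_reference_numbering(fam)
        mapped = {r.ref_index for r in mem.chains["A"]}
        assert mapped == set(range(1, 21)) - {10, 11, 12}

    def test_name_mismatch_rejected(self):
        ref = chain("ACDEFGHIK", "1ref", resolution=1.2)
        mem = chain("ACDEFGHIK", "2mem", resolution=2.0)
        mem.chains["A"][4].name = "TRP"  # residue name contradicts sequence
        fam = Family("F1", [ref, mem])
        build_reference_numbering(fam)
        assert [m.pdb_id for m in fam.members] == ["1ref"]
        assert fam.decisions and "RENUMBER_FAIL" in fam.decisions[0].reasons[0]

    def test_chain_assignment_matches_exhaustive_oracle(self):
        # two-chain reference; member chains must land on their best matches
        seq_a, seq_b = "ACDEFGHIKLMN", "QRSTVWYACDEF"
        ref = chain(seq_a, "1ref", resolution=1.0)
        ref.chains["B"] = chain(seq_b, "tmp0").chains["A"]
        for r in ref.chains["B"]:
            r.chain_id = "B"
        mem = chain(seq_a, "2mem", resolution=2.0)
        mem.chains["B"] = chain(seq_b, "tmp1").chains["A"]
        for r in mem.chains["B"]:
            r.chain_id = "B"
        fam = Family("F1", [ref, mem])
        build_reference_numbering(fam)
        assert not fam.decisions
        got = {mc: {r.ref_chain for r in mem.chains[mc]} for mc in mem.chains}
        # oracle: exhaustive assignment by exact sequence equality
        best = {}
        for mc, rc in itertools.product("AB", repeat=2):
            if mem is not None and \
                    "".join(r.one_letter for r in mem.chains[mc]) == \
                    "".join(r.one_letter for r in ref.chains[rc]):
                best.setdefault(mc, rc)
        assert got == {mc: {rc} for mc, rc in best.items()}


class TestHoloValidation:
    def _holo_fixture(self, **spec_kw):
        fx = make_family(FamilyFixtureSpec(seed=3, **spec_kw))
        return [s for s in load_fixture_structures(fx) if s.role == "holo"]

    def test_clean_structure_accepted(self):
        holo = self._holo_fixture()[0]
        d = validate_holo(holo)
        assert d.accepted and not d.reasons

    def test_resolution_over_cutoff_rejected(self):
        holo = self._holo_fixture()[0]
        holo.resolution = 2.6
        d = validate_holo(holo)
        assert not d.accepted and d.reasons == ["RESOLUTION"]
        assert validate_holo(holo, RunConfig(resolution_cutoff=3.0)).accepted

    def test_two_valid_ligands_rejected(self):
        holo = self._holo_fixture()[0]
        holo.ligands = holo.ligands * 2
        d = validate_holo(holo)
        assert d.reasons == ["MULTI_LIGAND"]

    def test_additive_in_binding_site_rejected(self):
        holo = self._holo_fixture()[0]
        # drop a foreign molecule right next to a contact residue
        contact_atom = holo.ligand.heavy_atoms[0].position
        holo.hets.append(HetRecord("EDO", "X", 700, "", [
            Atom("C1", "C", contact_atom + np.array([0.5, 0.0, 0.0]))], 62.07))
        d = validate_holo(holo)
        assert d.reasons == ["SITE_CONTAMINATION"]

    def test_missing_ligand_spec_is_an_error(self):
        holo = self._holo_fixture()[0]
        holo.ligand_specs = []
        with pytest.raises(ValueError, match="ligand spec"):
            validate_holo(holo)


class TestApoValidation:
    def _family_with_site(self, seed=3):
        fx = make_family(FamilyFixtureSpec(seed=seed))
        structs = load_fixture_structures(fx)
        fam = Family("F1", structs)
        build_reference_numbering(fam)
        holo = [s for s in fam.members if s.role == "holo"]
        site = unify_sites(holo, fam.members)
        apo = [s for s in fam.members if s.role == "apo"]
        return apo, site

    def test_waters_only_accepted(self):
        apo, site = self._family_with_site()
        d = validate_apo(apo[0], site, allowlist=set())
        assert d.accepted

    def test_heavy_het_needs_allowlist(self):
        apo, site = self._family_with_site()
        far = np.array([200.0, 200.0, 200.0])
        apo[0].hets.append(HetRecord("NAG", "X", 700, "", [Atom("C1", "C", far)],
                                     mol_weight=180.0))
        assert validate_apo(apo[0], site, set()).reasons == ["HET_DISALLOWED"]
        assert validate_apo(apo[0], site, {"NAG"}).accepted

    def test_light_het_passes_without_allowlist(self):
        apo, site = self._family_with_site()
        far = np.array([200.0, 200.0, 200.0])
        apo[0].hets.append(HetRecord("ACT", "X", 700, "", [Atom("C1", "C", far)],
                                     mol_weight=59.0))
        assert validate_apo(apo[0], site, set()).accepted

    def test_allowlisted_het_near_site_still_contaminates(self):
        apo, site = self._family_with_site()
        # place glycerol 4.0 A from a unified-site residue atom
        site_res = next(r for r in apo[0].residues()
                        if r.ref_index is not None
                        and (r.ref_chain, r.ref_index) in site.residue_ids)
        pos = site_res.atoms[-1].position + np.array([4.0, 0.0, 0.0])
        apo[0].hets.append(HetRecord("GOL", "X", 700, "", [Atom("C1", "C", pos)],
                                     mol_weight=92.09))
        d = validate_apo(apo[0], site, {"GOL"})
        assert d.reasons == ["SITE_CONTAMINATION"]

    def test_site_is_required(self):
        apo, _ = self._family_with_site()
        with pytest.raises(ValueError, match="unified site"):
            validate_apo(apo[0], None, set())


class TestCohortCuration:
    def test_decoy_contamination_drops_family_below_two_apo(self):
        # 3 apo members; decoys contaminate two of them -> family dies
        spec = FamilyFixtureSpec(
            seed=9,
            decoy_hets=[DecoyHet("MES", 195.2, "near_site", member=0),
                        DecoyHet("MES", 195.2, "near_site", member=1)])
        fx = make_family(spec)
        structs = load_fixture_structures(fx)
        fams, decisions = curate_cohort(structs, allowlist=set())
        assert fams == []
        reasons = {d.pdb_id: d.reasons for d in decisions}
        contaminated = [p for p, r in reasons.items() if "SITE_CONTAMINATION" in r]
        assert len(contaminated) == 2
        # the surviving member was individually fine but its family was not
        assert any("NO_FAMILY" in r for r in reasons.values())

    def test_remote_decoys_leave_family_intact(self):
        spec = FamilyFixtureSpec(
            seed=9, decoy_hets=[DecoyHet("GOL", 92.09, "remote", member=0)])
        structs = load_fixture_structures(make_family(spec))
        fams, decisions = curate_cohort(structs, allowlist={"GOL"})
        assert len(fams) == 1
        assert fams[0].n_apo == 3 and fams[0].n_holo == 3
        assert all(d.accepted for d in decisions)

    def test_curation_is_deterministic(self):
        spec = FamilyFixtureSpec(seed=4)
        structs = load_fixture_structures(make_family(spec))
        runs = []
        for _ in range(2):
            fams, decisions = curate_cohort(
                load_fixture_structures(make_family(spec)), set())
            runs.append([(d.pdb_id, d.accepted, tuple(d.reasons))
                         for d in decisions])
        assert runs[0] == runs[1]

    def test_every_surviving_family_has_two_plus_two(self):
        from apoholo.synthetic import make_cohort
        structs = []
        for fx in make_cohort(n_families=4, seed=21):
            structs.extend(load_fixture_structures(fx))
        # plant a violation: remove all but one apo member of one family
        doomed = {s.pdb_id for s in structs if s.pdb_id.startswith("02a")}
        structs = [s for s in structs if s.pdb_id not in sorted(doomed)[1:]]
        fams, _ = curate_cohort(structs, set())
        assert all(f.n_apo >= 2 and f.n_holo >= 2 for f in fams)
        assert len(fams) == 3
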