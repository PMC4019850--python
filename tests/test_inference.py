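"""Bridge-path enumeration, the five filter rules, and sign propagation."""

import numpy as np
import pytest

from _oracles import exhaustive_bridge_paths
from phosbridge.inference import (
    InferenceConfig,
    enumerate_bridge_paths,
    filter_functional_sites,
    filter_phenotype_consistency,
    filter_residue_compatibility,
    filter_substrate_role,
    infer_substrates,
    max_steps_for,
    predict_knockdown_sign,
)
from phosbridge.interactome import PPINetwork
from phosbridge.types import (
    Interaction,
    PathwayModel,
    PhenotypeRecord,
    PhosphataseInfo,
    PhosphoSite,
    ValidationError,
)


def _net(*pairs):
    net = PPINetwork()
    for a, b in pairs:
        net.add_interaction(Interaction(a, b))
    return net


def _pathway(members, edges=(), roles=None, readouts=None):
    readouts = readouts or {sorted(members)[0]}
    return PathwayModel(members=set(members) | set(readouts),
                        edges=list(edges), roles=roles or {},
                        readouts=set(readouts))


class TestMaxSteps:
    def test_monomeric_phosphatase_gets_two_steps(self):
        assert max_steps_for(PhosphataseInfo("DUSP18", "tyrosine")) == 2

    @pytest.mark.parametrize("pid,group", [("PPP2CA", "PP2A"),
                                           ("PPP3CA", "CALCINEURIN")])
    def test_holoenzyme_subunits_get_three_steps(self, pid, group):
        info = PhosphataseInfo(pid, "ser_thr", holoenzyme_group=group)
        assert max_steps_for(info) == 3


class TestEnumerateBridgePaths:
    def test_bridge_to_pathway_member(self):
        net = _net(("DUSP18", "CAT"), ("CAT", "SHP2"))
        pathway = _pathway({"SHP2"}, readouts={"SHP2"})
        paths = enumerate_bridge_paths(
            net, PhosphataseInfo("DUSP18", "dual"), pathway, 2
        )
        assert paths == [("DUSP18", "CAT", "SHP2")]

    def test_isolated_phosphatase_has_no_paths(self):
        net = _net(("A", "B"))
        net.add_node("LONER")
        pathway = _pathway({"B"}, readouts={"B"})
        assert enumerate_bridge_paths(
            net, PhosphataseInfo("LONER", "dual"), pathway, 3
        ) == []

    def test_pathway_member_terminates_path(self):
        # X is a member: paths may end at X but never pass through it
        net = _net(("P", "X"), ("X", "Y"), ("Y", "Z"))
        pathway = _pathway({"X", "Z"}, readouts={"X"})
        paths = enumerate_bridge_paths(
            net, PhosphataseInfo("P", "dual"), pathway, 3
        )
        assert ("P", "X") in paths
        assert all("X" not in p[1:-1] for p in paths)
        assert ("P", "X", "Y", "Z") not in paths

    def test_absent_bait_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_bridge_paths(_net(("A", "B")),
                                   PhosphataseInfo("Q", "dual"),
                                   _pathway({"B"}, readouts={"B"}), 2)

    @pytest.mark.parametrize("seed", range(0, 200, 1))
    def test_matches_exhaustive_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        nodes = [f"V{i}" for i in range(n)]
        net = PPINetwork()
        for node in nodes:
            net.add_node(node)
        adjacency = {node: set() for node in nodes}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    net.add_interaction(Interaction(nodes[i], nodes[j]))
                    adjacency[nodes[i]].add(nodes[j])
                    adjacency[nodes[j]].add(nodes[i])
        bait = nodes[0]
        members = {node for node in nodes[1:] if rng.random() < 0.3}
        if not members:
            members = {nodes[-1]}
        pathway = _pathway(members, readouts={sorted(members)[0]})
        max_steps = int(rng.integers(1, 4))
        ours = enumerate_bridge_paths(
            net, PhosphataseInfo(bait, "dual"), pathway, max_steps
        )
        assert ours == exhaustive_bridge_paths(adjacency, bait, members,
                                               max_steps)


class TestRuleFilters:
    PATHWAY = _pathway(
        {"SHP2", "RAF1", "GLUE"},
        roles={"SHP2": "phosphatase", "RAF1": "kinase", "GLUE": "other"},
        readouts={"RAF1"},
    )

    def test_substrate_role_accepts_enzymes_and_scaffolds(self):
        assert filter_substrate_role("SHP2", self.PATHWAY)
        assert filter_substrate_role("RAF1", self.PATHWAY)
        assert not filter_substrate_role("GLUE", self.PATHWAY)

    def test_functional_sites_drop_unknown_effects(self):
        sites = [
            PhosphoSite("SHP2", "Y", 542, "activating"),
            PhosphoSite("SHP2", "S", 576, "unknown"),
            PhosphoSite("RAF1", "T", 401, "inhibiting"),
        ]
        kept = filter_functional_sites("SHP2", sites)
        assert [s.position for s in kept] == [542]
        assert filter_functional_sites("GLUE", sites) == []

    def test_residue_compatibility_by_enzyme_class(self):
        tyr = PhosphataseInfo("PTP", "tyrosine")
        st_ = PhosphataseInfo("PPP3CA", "ser_thr", "CALCINEURIN")
        dual = PhosphataseInfo("DUSP", "dual")
        s259 = PhosphoSite("X", "S", 259, "inhibiting")
        t401 = PhosphoSite("RAF1", "T", 401, "inhibiting")
        y204 = PhosphoSite("X", "Y", 204, "activating")
        assert filter_residue_compatibility(tyr, [s259]) == []
        assert filter_residue_compatibility(st_, [t401]) == [t401]
        assert filter_residue_compatibility(dual, [y204, t401]) == [y204, t401]


class TestSignPropagation:
    def test_substrate_equals_readout_identity(self):
        pathway = _pathway({"E"}, readouts={"E"})
        site = PhosphoSite("E", "Y", 1, "activating")
        assert predict_knockdown_sign("E", site, pathway, "E") == {+1}

    def test_single_positive_route(self):
        pathway = _pathway({"S", "R"}, edges=[("S", "R", +1)],
                           readouts={"R"})
        site = PhosphoSite("S", "Y", 1, "activating")
        assert predict_knockdown_sign("S", site, pathway, "R") == {+1}
        site = PhosphoSite("S", "Y", 1, "inhibiting")
        assert predict_knockdown_sign("S", site, pathway, "R") == {-1}

    def test_disagreeing_routes_yield_both_signs(self):
        pathway = _pathway(
            {"S", "M", "R"},
            edges=[("S", "R", +1), ("S", "M", +1), ("M", "R", -1)],
            readouts={"R"},
        )
        site = PhosphoSite("S", "Y", 1, "activating")
        assert predict_knockdown_sign("S", site, pathway, "R") == {+1, -1}

    def test_unreachable_readout_yields_empty_set(self):
        pathway = _pathway({"S", "R"}, readouts={"R"})
        site = PhosphoSite("S", "Y", 1, "activating")
        assert predict_knockdown_sign("S", site, pathway, "R") == set()

    def test_depth_limit_hides_long_routes(self):
        chain = [("A", "B", +1), ("B", "C", +1), ("C", "D", +1),
                 ("D", "E", +1), ("E", "R", +1)]
        pathway = _pathway({"A", "B", "C", "D", "E", "R"}, edges=chain,
                           readouts={"R"})
        site = PhosphoSite("A", "Y", 1, "activating")
        assert predict_knockdown_sign("A", site, pathway, "R",
                                      max_pathway_depth=4) == set()
        assert predict_knockdown_sign("A", site, pathway, "R",
                                      max_pathway_depth=5) == {+1}


class TestPhenotypeConsistency:
    PATHWAY = _pathway({"S", "R"}, edges=[("S", "R", +1)], readouts={"R"})
    SITE = [PhosphoSite("S", "Y", 1, "activating")]
    INFO = PhosphataseInfo("P", "tyrosine")

    def _run(self, observed, mode="permissive", sites=None):
        phenotypes = [PhenotypeRecord("P", "R", observed)]
        return filter_phenotype_consistency(
            self.INFO, "S", sites if sites is not None else self.SITE,
            self.PATHWAY, phenotypes, mode=mode,
        )

    def test_matching_sign_passes(self):
        passed, detail = self._run(+1)
        assert passed and detail["R"] == ((+1,), +1)

    def test_mismatched_sign_fails(self):
        assert not self._run(-1)[0]

    def test_ambiguous_prediction_strict_vs_permissive(self):
        pathway = _pathway(
            {"S", "M", "R"},
            edges=[("S", "R", +1), ("S", "M", +1), ("M", "R", -1)],
            readouts={"R"},
        )
        phenotypes = [PhenotypeRecord("P", "R", +1)]
        strict, _ = filter_phenotype_consistency(
            self.INFO, "S", self.SITE, pathway, phenotypes, mode="strict"
        )
        permissive, _ = filter_phenotype_consistency(
            self.INFO, "S", self.SITE, pathway, phenotypes, mode="permissive"
        )
        assert not strict and permissive

    def test_no_phenotype_records_fails_with_empty_detail(self):
        passed, detail = filter_phenotype_consistency(
            self.INFO, "S", self.SITE, self.PATHWAY, [], mode="permissive"
        )
        assert not passed and detail == {}

    def test_no_compatible_sites_fails(self):
        assert not self._run(+1, sites=[])[0]


class TestInferOnMiniBundle:
    def _infer(self, bundle, net, bait, **kwargs):
        cfg = InferenceConfig(sequences=bundle.sequences, **kwargs)
        return infer_substrates(net, bundle.phosphatases[bait],
                                bundle.pathway, bundle.sites,
                                bundle.phenotypes, cfg)

    def test_dusp18_catalase_shp2_accepted(self, mini_bundle, mini_network):
        net, _ = mini_network
        hyps = self._infer(mini_bundle, net, "DUSP18")
        accepted = [h for h in hyps if h.accepted]
        assert [h.path for h in accepted] == [("DUSP18", "CAT", "SHP2")]
        assert accepted[0].steps == 2

    def test_dusp18_needs_both_binding_steps(self, mini_bundle, mini_network):
        net, _ = mini_network
        hyps = self._infer(mini_bundle, net, "DUSP18", max_steps_override=1)
        assert not any(h.accepted for h in hyps)

    def test_dusp26_scrib_erk_permissive_only(self, mini_bundle,
                                              mini_network):
        net, _ = mini_network
        permissive = self._infer(mini_bundle, net, "DUSP26")
        accepted = [h for h in permissive if h.accepted]
        assert [h.path for h in accepted] == [("DUSP26", "SCRIB", "ERK")]
        # the ERK -| RAF1 feedback makes the prediction sign-ambiguous
        assert accepted[0].consistency_detail["ERK_P"] == ((-1, +1), -1)
        strict = self._infer(mini_bundle, net, "DUSP26", mode="strict")
        assert not any(h.accepted for h in strict)

    def test_ppp3ca_three_step_holoenzyme_path(self, mini_bundle,
                                               mini_network):
        net, _ = mini_network
        hyps = self._infer(mini_bundle, net, "PPP3CA")
        accepted = [h for h in hyps if h.accepted]
        assert [h.path for h in accepted] == [
            ("PPP3CA", "PPP3R1", "AKAP5", "RAF1")
        ]
        assert accepted[0].steps == 3

    def test_mislabeled_tyrosine_ppp3ca_rejected(self, mini_bundle,
                                                 mini_network):
        """A tyrosine-specific enzyme cannot explain removal of RAF1 Thr401."""
        net, _ = mini_network
        wrong = PhosphataseInfo("PPP3CA", "tyrosine",
                                holoenzyme_group="CALCINEURIN")
        hyps = infer_substrates(net, wrong, mini_bundle.pathway,
                                mini_bundle.sites, mini_bundle.phenotypes,
                                InferenceConfig())
        target = [h for h in hyps if h.substrate == "RAF1"]
        assert target and not any(h.accepted for h in target)
        assert all(not h.filters_passed["residue_compatibility"]
                   for h in target)

    def test_motif_support_attached_to_hypotheses(self, mini_bundle,
                                                  mini_network):
        net, _ = mini_network
        grb2 = [h for h in self._infer(mini_bundle, net, "PTPN21")
                if h.substrate == "GRB2"][0]
        kinds = {(node, kind) for node, kind, _ in grb2.motif_support}
        assert ("PTPN21", "sh3_class_ii") in kinds

    def test_inference_invariant_to_input_permutation(self, mini_bundle,
                                                      mini_network):
        net, _ = mini_network
        base = self._infer(mini_bundle, net, "DUSP26")
        shuffled_sites = list(reversed(mini_bundle.sites))
        shuffled_phen = list(reversed(mini_bundle.phenotypes))
        again = infer_substrates(net, mini_bundle.phosphatases["DUSP26"],
                                 mini_bundle.pathway, shuffled_sites,
                                 shuffled_phen,
                                 InferenceConfig(
                                     sequences=mini_bundle.sequences))
        assert [(h.path, h.filters_passed, h.accepted) for h in base] == [
            (h.path, h.filters_passed, h.accepted) for h in again
        ]
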