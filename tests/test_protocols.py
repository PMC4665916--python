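"""Join protocols: step counts, oracle equivalence, confidentiality, SSO."""

import pytest

from pseudokit.backends import AuthorizationError
from pseudokit.model import (
    Namespace,
    datasets_equivalent,
    integrate,
    pseudonymize_two_tier,
)
from pseudokit.protocols import Client, Message, assert_confidential
from pseudokit.synth import GeneratorSpec, generate_registry
from pseudokit.system import deploy


def oracle_dataset(registry):
    """Independent reconstruction path: separate with core_model, rejoin."""
    ds = registry.to_dataset()
    m, p, mp = pseudonymize_two_tier(ds, Namespace("oa"), Namespace("ob"), rng_seed=99)
    return integrate(m, p, mp).dataset


class TestIndirectJoin:
    def test_six_steps_all_messages_via_client(self, indirect_system, registry10,
                                               make_client):
        client = make_client(indirect_system, registry10, "monitor")
        view, t = client.join_indirect_single({"subject_index": 0})
        assert t.step_count == 6
        assert t.message_count == 6
        assert all(
            s.visible_to_client for s in t.steps if isinstance(s, Message)
        )
        route = [(s.frm, s.to) for s in t.steps]
        assert route[0] == ("client", "primary")
        assert route[-1] == ("secondary", "client")

    def test_view_matches_integrate_oracle(self, indirect_system, registry10,
                                           make_client):
        client = make_client(indirect_system, registry10, "monitor")
        oracle = oracle_dataset(registry10).content_multiset()
        for i in range(len(registry10.subjects)):
            view, _ = client.join_indirect_single({"subject_index": i})
            row_content = view.to_dataset().content_multiset()
            assert len(row_content) == 1
            assert row_content[0] in oracle

    def test_no_server_persists_temp_mappings(self, indirect_system, registry10,
                                              make_client):
        client = make_client(indirect_system, registry10, "monitor")
        for i in range(3):
            client.join_indirect_single({"subject_index": i})
        client.list_view()
        assert indirect_system.primary.temp_map == {}
        assert indirect_system.secondary.temp_map == {}

    def test_transcript_confidential(self, indirect_system, registry10, make_client):
        client = make_client(indirect_system, registry10, "monitor")
        _, t = client.join_indirect_single({"subject_index": 1})
        report = assert_confidential(t, indirect_system.internal_pseudonym_values())
        assert report.ok


class TestDirectJoin:
    def test_nine_steps_at_least_seven_messages(self, direct_system, registry10,
                                                make_client):
        client = make_client(direct_system, registry10, "monitor")
        view, t = client.join_direct_single({"subject_index": 0})
        assert t.step_count == 9
        assert t.message_count >= 7

    def test_view_matches_oracle_for_every_subject(self, direct_system, registry10,
                                                   make_client):
        client = make_client(direct_system, registry10, "monitor")
        oracle = oracle_dataset(registry10).content_multiset()
        for i in range(len(registry10.subjects)):
            view, _ = client.join_direct_single({"subject_index": i})
            content = view.to_dataset().content_multiset()
            assert content[0] in oracle

    def test_answer_routed_through_mapping_service(self, direct_system, registry10,
                                                   make_client):
        client = make_client(direct_system, registry10, "monitor")
        _, t = client.join_direct_single({"subject_index": 0})
        hops = [(s.frm, s.to) for s in t.steps if isinstance(s, Message)]
        assert ("primary", "mapping") in hops
        assert ("mapping", "secondary") in hops
        assert ("primary", "secondary") not in hops

    def test_temp_mapping_persisted_then_retired(self, direct_system, registry10,
                                                 make_client):
        client = make_client(direct_system, registry10, "monitor")
        client.join_direct_single({"subject_index": 0})
        assert len(direct_system.primary.temp_map) == 1
        (entry,) = direct_system.primary.temp_map.values()
        assert entry.status == "retired"

    def test_server_to_server_messages_invisible_to_client(self, direct_system,
                                                           registry10, make_client):
        client = make_client(direct_system, registry10, "monitor")
        _, t = client.join_direct_single({"subject_index": 0})
        invisible = [
            s for s in t.steps
            if isinstance(s, Message) and not s.visible_to_client
        ]
        assert len(invisible) == 3
        assert all("client" not in (s.frm, s.to) for s in invisible)


class TestListView:
    def test_monitor_sees_all_subjects(self, indirect_system, registry10, make_client):
        client = make_client(indirect_system, registry10, "monitor")
        view, t = client.list_view()
        assert len(view.rows) == 10
        assert t.message_count == 6  # three batch rounds
        assert datasets_equivalent(view.to_dataset(), oracle_dataset(registry10))

    def test_physician_sees_only_own_site(self, indirect_system, registry10,
                                          make_client):
        client = make_client(indirect_system, registry10, "physician", "site-01")
        view, _ = client.list_view()
        # 10 subjects round-robin over 3 sites: site-01 holds 4
        assert len(view.rows) == 4
        assert all(r["master"]["institution"] == "site-01" for r in view.rows)

    def test_empty_registry_short_circuits(self, make_client):
        registry = generate_registry(GeneratorSpec(n_subjects=0, seed=1))
        system = deploy(registry, mode="indirect", seed=1)
        client = make_client(system, registry, "monitor")
        view, t = client.list_view()
        assert view.rows == []
        assert t.message_count == 2  # only the primary round runs


class TestCreateEcrf:
    def test_creates_document_and_at_most_one_pair(self, indirect_system, registry10,
                                                   make_client):
        client = make_client(indirect_system, registry10, "physician", "site-01")
        nodes_before = len(indirect_system.secondary.store.all())
        pairs_before = len(indirect_system.mapping_service.table)
        ref, t = client.create_ecrf(
            {"subject_index": 0}, "followup_visit",
            {"visit_no": "9", "symptom_score": "5", "medication": "none"},
        )
        assert ref.startswith("t-")
        assert len(indirect_system.secondary.store.all()) == nodes_before + 1
        assert len(indirect_system.mapping_service.table) - pairs_before <= 1

    def test_credentials_only_in_first_request(self, indirect_system, registry10,
                                               make_client):
        client = make_client(indirect_system, registry10, "physician", "site-01")
        _, t = client.create_ecrf({"subject_index": 0}, "followup_visit",
                                  {"visit_no": "1", "symptom_score": "2",
                                   "medication": "none"})
        messages = [s for s in t.steps if isinstance(s, Message)]
        assert '"password"' in messages[0].body_text
        for m in messages[1:]:
            assert '"password"' not in m.body_text
        assert client.credential_submissions == 1

    def test_monitor_denied_at_primary_with_zero_state_change(
        self, indirect_system, registry10, make_client
    ):
        client = make_client(indirect_system, registry10, "monitor")
        nodes_before = len(indirect_system.secondary.store.all())
        pairs_before = len(indirect_system.mapping_service.table)
        with pytest.raises(AuthorizationError, match="primary"):
            client.create_ecrf({"subject_index": 0}, "followup_visit",
                               {"visit_no": "1", "symptom_score": "1",
                                "medication": "none"})
        assert len(indirect_system.secondary.store.all()) == nodes_before
        assert len(indirect_system.mapping_service.table) == pairs_before

    def test_created_document_appears_in_subsequent_join(self, indirect_system,
                                                         registry10, make_client):
        client = make_client(indirect_system, registry10, "physician", "site-01")
        client.create_ecrf({"subject_index": 0}, "followup_visit",
                           {"visit_no": "7", "symptom_score": "3",
                            "medication": "coq10"})
        view, _ = client.join_indirect_single({"subject_index": 0})
        payload = view.rows[0]["payload"]
        assert any(v == "coq10" for v in payload.values())


class TestSso:
    def test_single_credential_submission_across_many_hops(self, indirect_system,
                                                           registry10, make_client):
        client = make_client(indirect_system, registry10, "monitor")
        for i in range(4):
            client.join_indirect_single({"subject_index": i})
        client.list_view()
        assert client.credential_submissions == 1


class TestFaultInjection:
    def test_disabled_substitution_is_caught_by_verifier(self, registry10,
                                                         make_client):
        system = deploy(registry10, mode="indirect", seed=13)
        system.primary.substitute_temp_ids = False
        client = make_client(system, registry10, "monitor")
        _, t = client.join_indirect_single({"subject_index": 0})
        report = assert_confidential(t, system.internal_pseudonym_values())
        assert not report.ok
        assert report.violations

    def test_empty_transcript_gives_empty_report(self, indirect_system):
        from pseudokit.protocols import Transcript

        report = assert_confidential(
            Transcript(), indirect_system.internal_pseudonym_values()
        )
        assert report.ok
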