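import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subcell.annotations import FunDVector, GOVector
from subcell.config import RunConfig
from subcell.ensemble import (
    FragmentError,
    MissingInputError,
    PredictionResult,
    ProteinRecord,
    ProteinResources,
    VoteTally,
    go_engine_predict,
    multilabel_select,
    predict,
    seq_engine_predict,
)
from subcell.evaluation import build_go_library, build_seq_libraries
from subcell.profiles import PSSMProfile
from subcell.synthdata import SyntheticConfig, make_benchmark


class TestMultilabelSelect:
    def test_theta_zero_unique_maximum_is_singleton(self):
        tally = VoteTally({1: 7, 2: 3}, 10)
        assert multilabel_select(tally, 0.0) == {1}

    def test_theta_zero_returns_all_tied_maxima(self):
        tally = VoteTally({1: 5, 2: 5}, 10)
        assert multilabel_select(tally, 0.0) == {1, 2}

    def test_band_worked_example(self):
        tally = VoteTally({1: 6, 2: 3, 3: 1}, 10)
        assert multilabel_select(tally, 0.3) == {1, 2}

    def test_zero_vote_locations_never_enter(self):
        tally = VoteTally({2: 10}, 10)
        assert multilabel_select(tally, 0.9) == {2}

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(0, 20), min_size=2, max_size=6).filter(
            lambda v: sum(v) > 0
        ),
        st.floats(0.0, 0.99),
        st.floats(0.0, 0.99),
    )
    def test_monotone_in_theta(self, votes, t1, t2):
        tally = VoteTally(
            {i + 1: v for i, v in enumerate(votes) if v}, sum(votes)
        )
        lo, hi = sorted([t1, t2])
        assert multilabel_select(tally, lo) <= multilabel_select(tally, hi)


class TestVoteTally:
    def test_vote_conservation_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            VoteTally({1: 3, 2: 3}, 10)


@pytest.fixture(scope="module")
def bench():
    return make_benchmark(
        SyntheticConfig(n_proteins=40, n_locations=3, orphan_frac=0.3, seed=7)
    )


@pytest.fixture(scope="module")
def go_library(bench):
    return build_go_library(bench)


@pytest.fixture(scope="module")
def seq_libraries(bench):
    return build_seq_libraries(bench)


class TestGOEngine:
    def test_ten_members_vote(self, bench, go_library):
        entry = next(p for p in bench.proteins if p.go_indices)
        vec = GOVector(entry.protein_id, entry.go_indices)
        res = go_engine_predict(vec, go_library, theta=0.2)
        assert res.engine == "GO"
        assert res.tally.n_members == 10
        assert sum(res.tally.votes.values()) == 10

    def test_query_inside_one_cluster_is_recovered(self, bench, go_library):
        entry = next(
            p for p in bench.proteins if p.go_indices and len(p.labels) == 1
        )
        vec = GOVector(entry.protein_id, entry.go_indices)
        res = go_engine_predict(vec, go_library, theta=0.2)
        assert res.predicted_locations == set(entry.labels)

    def test_predicted_locations_received_votes(self, bench, go_library):
        for entry in bench.proteins[:10]:
            if not entry.go_indices:
                continue
            vec = GOVector(entry.protein_id, entry.go_indices)
            res = go_engine_predict(vec, go_library, theta=0.4)
            assert res.predicted_locations <= set(res.tally.votes)

    def test_unproductive_query_is_rejected(self, go_library):
        vec = GOVector("ghost", frozenset())
        with pytest.raises(ValueError, match="productive"):
            go_engine_predict(vec, go_library, theta=0.2)

    def test_deterministic(self, bench, go_library):
        entry = next(p for p in bench.proteins if p.go_indices)
        vec = GOVector(entry.protein_id, entry.go_indices)
        r1 = go_engine_predict(vec, go_library, theta=0.2)
        r2 = go_engine_predict(vec, go_library, theta=0.2)
        assert r1 == r2


class TestSeqEngine:
    def test_500_members_at_full_length(self, bench, seq_libraries):
        entry = bench.proteins[0]
        fund = FunDVector(entry.protein_id, entry.fund_indices)
        res = seq_engine_predict(fund, entry.profile, seq_libraries, 0.2)
        assert res.tally.n_members == 500
        assert sum(res.tally.votes.values()) == 500
        assert res.warnings == ()

    def test_single_location_library_wins_everything(self, bench):
        from subcell.evaluation import BenchmarkDataset

        kept = [p for p in bench.proteins if p.labels == (2,)]
        sub = BenchmarkDataset(kept, bench.location_names)
        libs = build_seq_libraries(sub)
        entry = kept[0]
        fund = FunDVector(entry.protein_id, entry.fund_indices)
        res = seq_engine_predict(fund, entry.profile, libs, 0.2)
        assert res.predicted_locations == {2}
        assert res.tally.votes == {2: res.tally.n_members}

    def test_short_profile_truncates_lag_range_with_warning(self):
        short = make_benchmark(
            SyntheticConfig(
                n_proteins=24, n_locations=2, min_len=30, max_len=30, seed=3,
                orphan_frac=0.0,
            )
        )
        libs = build_seq_libraries(short)
        assert set(libs) == set(range(30))
        entry = short.proteins[0]
        fund = FunDVector(entry.protein_id, entry.fund_indices)
        res = seq_engine_predict(fund, entry.profile, libs, 0.2)
        assert res.tally.n_members == 10 * 30
        assert any("truncated" in w for w in res.warnings)


class TestRouting:
    def _resources(self, bench, entry, with_hits):
        hits = pd.DataFrame(
            [
                (entry.protein_id, q.protein_id, 90.0, 100, 0, 0, 1, 100, 1,
                 100, 1e-30, 200.0)
                for q in bench.proteins
                if q.labels == entry.labels and q.protein_id != entry.protein_id
            ],
            columns=(
                "qseqid sseqid pident length mismatch gapopen qstart qend "
                "sstart send evalue bitscore"
            ).split(),
        )
        go_table = {
            p.protein_id: p.go_indices for p in bench.proteins
        }
        raw = np.rint(entry.profile.values * 3).astype(int)
        profile = PSSMProfile(entry.protein_id, entry.sequence, raw)
        return ProteinResources(
            blast_hits=hits if with_hits else hits.iloc[0:0],
            go_table=go_table,
            domain_hits=[(i, 1e-8) for i in sorted(entry.fund_indices)],
            profile=profile,
        )

    def test_productive_query_routes_to_go(self, bench, go_library, seq_libraries):
        entry = next(p for p in bench.proteins if p.go_indices)
        record = ProteinRecord(entry.protein_id, entry.sequence)
        res = predict(
            record, self._resources(bench, entry, True), go_library,
            seq_libraries,
        )
        assert res.engine == "GO"

    def test_empty_homology_set_routes_to_seq(self, bench, go_library, seq_libraries):
        entry = bench.proteins[0]
        record = ProteinRecord(entry.protein_id, entry.sequence)
        res = predict(
            record, self._resources(bench, entry, False), go_library,
            seq_libraries,
        )
        assert res.engine == "SEQ"

    def test_fragment_is_rejected(self, bench, go_library, seq_libraries):
        record = ProteinRecord("frag", "ACDEFGHIKLMNPQRSTVWY" * 2)  # 40 aa
        with pytest.raises(FragmentError, match="fragment"):
            predict(record, ProteinResources(), go_library, seq_libraries)

    def test_missing_profile_is_a_named_error(self, bench, go_library, seq_libraries):
        entry = bench.proteins[0]
        record = ProteinRecord(entry.protein_id, entry.sequence)
        resources = self._resources(bench, entry, False)
        resources.profile = None
        with pytest.raises(MissingInputError, match="PSSM"):
            predict(record, resources, go_library, seq_libraries)
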