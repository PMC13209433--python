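import math

import numpy as np
import pytest

from shapedock import (ComplexSpec, DescriptorConfig, C3DDVector, build_library,
                       c3dd, load_library, save_library, search, similarity)
from shapedock.docking import BoxSpec
from shapedock.errors import LibraryError, MetadataMismatchError
from shapedock.fixtures import make_library, make_molecule, mock_engine, FixtureSpec
from shapedock.similarity import LibraryEntry, DescriptorLibrary
from shapedock.structure_io import read_molecule


def _vec(values, meta=None):
    return C3DDVector(values=np.asarray(values, float), metadata=meta or {})


def test_identity_scores_one_exactly():
    v = _vec([3.0, 2.0, 1.5, 0.7, 0.9, 0.8, 0.95, 150.0, 210.0, 0.71])
    assert similarity(v, v) == 1.0


def test_componentwise_doubling_scores_half_exactly():
    a = _vec([3.0, 2.0, 1.5, 0.7, 0.9, 0.8, 0.95, 150.0, 210.0, 0.71])
    b = _vec(a.values * 2.0)
    assert similarity(a, b) == 0.5


def test_random_pairs_match_brute_force_and_symmetry():
    rng = np.random.default_rng(21)
    for _ in range(100):
        a = _vec(rng.uniform(0.1, 10.0, 10))
        b = _vec(rng.uniform(0.1, 10.0, 10))
        expected = sum(min(x, y) / max(x, y) for x, y in zip(a.values, b.values)) / 10.0
        assert similarity(a, b) == pytest.approx(expected, rel=1e-14)
        assert similarity(a, b) == similarity(b, a)
        assert 0.0 <= similarity(a, b) <= 1.0


def test_zero_and_sign_conventions():
    base = [1.0] * 10
    a, b = base.copy(), base.copy()
    a[3], b[3] = 0.0, 0.0           # both zero -> term is 1
    assert similarity(_vec(a), _vec(b)) == 1.0
    b[3] = 2.0                       # exactly one zero -> term is 0
    assert similarity(_vec(a), _vec(b)) == 0.9
    a[3], b[3] = -1.5, 1.5           # opposite signs -> term is 0
    assert similarity(_vec(a), _vec(b)) == 0.9
    a[3], b[3] = -2.0, -1.0          # same negative sign -> magnitude ratio
    assert similarity(_vec(a), _vec(b)) == pytest.approx(0.95)


def test_metadata_mismatch_raises():
    a = _vec([1.0] * 10, {"spacing": "0.3"})
    b = _vec([1.0] * 10, {"spacing": "0.2"})
    with pytest.raises(MetadataMismatchError):
        similarity(a, b)


@pytest.fixture(scope="module")
def small_library(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("lib")
    specs = make_library(seed=7, n_targets=3, outdir=outdir)
    engine = mock_engine(seed=7)
    library = build_library(specs, DescriptorConfig(spacing=0.4), engine=engine)
    return specs, engine, library


def test_build_library_entries_complete(small_library):
    specs, engine, library = small_library
    assert len(library) == 3
    assert len({e.entry_id for e in library.entries}) == 3
    for e in library.entries:
        assert e.vector.values.shape == (10,)
        assert math.isfinite(e.score_b)


def test_build_library_score_b_matches_mock(small_library):
    specs, engine, library = small_library
    for spec, entry in zip(specs, library.entries):
        ligand = read_molecule(spec.ligand_file)
        assert entry.score_b == engine.dock(spec.receptor_file, ligand, entry.box).score


def test_build_library_is_deterministic(small_library, tmp_path):
    specs, engine, _ = small_library
    lib1 = build_library(specs, DescriptorConfig(spacing=0.4), engine=engine)
    lib2 = build_library(specs, DescriptorConfig(spacing=0.4), engine=engine)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    save_library(lib1, p1)
    save_library(lib2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_build_library_skips_failing_entries(small_library, tmp_path):
    specs, engine, _ = small_library
    broken = specs + [ComplexSpec(entry_id="BAD", receptor_file="r.pdb",
                                  ligand_file=str(tmp_path / "missing.sdf"))]
    library = build_library(broken, DescriptorConfig(spacing=0.4), engine=engine)
    assert len(library) == 3
    with pytest.raises(LibraryError):
        build_library([broken[-1]], DescriptorConfig(spacing=0.4))


def test_library_round_trip(small_library, tmp_path):
    _, _, library = small_library
    path = tmp_path / "lib.tsv"
    save_library(library, path)
    back = load_library(path)
    assert back.metadata == library.metadata
    for a, b in zip(library.entries, back.entries):
        assert a.entry_id == b.entry_id
        assert np.allclose(a.vector.values, b.vector.values, rtol=1e-9)
        assert a.score_b == pytest.approx(b.score_b, rel=1e-9)
        assert a.box.center == pytest.approx(b.box.center, rel=1e-9)


def test_pending_score_b_survives_round_trip(small_library, tmp_path):
    specs, _, _ = small_library
    library = build_library(specs, DescriptorConfig(spacing=0.4))  # no engine
    path = tmp_path / "pending.tsv"
    save_library(library, path)
    back = load_library(path)
    assert all(e.score_b_pending for e in back.entries)


def test_self_retrieval(small_library):
    specs, _, library = small_library
    cfg = DescriptorConfig(spacing=0.4)
    for spec in specs:
        query = c3dd(read_molecule(spec.ligand_file), cfg)
        hits = search([query], library, top_k=3)
        assert hits[0].entry_id == spec.entry_id
        assert hits[0].similarity == 1.0
        assert hits[0].similarity_rank == 1


def test_search_top1_matches_brute_force(small_library):
    specs, _, library = small_library
    cfg = DescriptorConfig(spacing=0.4)
    query = c3dd(make_molecule(FixtureSpec(seed=99, kind="random_cloud", n_atoms=10)), cfg)
    hits = search([query], library, top_k=1)
    best = min(library.entries, key=lambda e: (-similarity(query, e.vector), e.entry_id))
    assert len(hits) == 1 and hits[0].entry_id == best.entry_id


def test_search_reports_best_conformer():
    meta = {"spacing": "0.3"}
    entry_vec = _vec([2.0] * 10, meta)
    entry = LibraryEntry(entry_id="E1", target_id="t", target_name="t", pdb_id="x",
                         ligand_file="l.sdf", receptor_file="r.pdb",
                         box=BoxSpec((0, 0, 0), (16, 16, 16)), vector=entry_vec,
                         score_b=-5.0)
    library = DescriptorLibrary(entries=[entry], metadata=meta)
    conf1 = _vec([1.0] * 10, meta)   # sim 0.5
    conf2 = _vec([2.0] * 10, meta)   # sim 1.0
    hits = search([conf1, conf2], library)
    assert hits[0].best_query_conformer == 1
    assert hits[0].similarity == 1.0


def test_search_ranks_are_contiguous_and_sorted(small_library):
    _, _, library = small_library
    cfg = DescriptorConfig(spacing=0.4)
    query = c3dd(make_molecule(FixtureSpec(seed=5, kind="random_cloud", n_atoms=9)), cfg)
    hits = search([query], library)
    assert [h.similarity_rank for h in hits] == list(range(1, len(hits) + 1))
    sims = [h.similarity for h in hits]
    assert sims == sorted(sims, reverse=True)


def test_search_errors():
    with pytest.raises(LibraryError):
        search([], DescriptorLibrary(entries=[], metadata={}))
    with pytest.raises(LibraryError):
        search([_vec([1.0] * 10)], DescriptorLibrary(entries=[], metadata={}))
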