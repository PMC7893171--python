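import numpy as np
import pytest

from dimerscope.cluster import (
    extract_dimers,
    gromos_cluster,
    name_interface,
    pairwise_rmsd_matrix,
    symmetrize,
    symmetry_pairs,
)
from dimerscope.geometry import kabsch
from dimerscope.synthetic.membrane import make_c2_dimer_frames
from dimerscope.topology import Frame


def naive_gromos(rmsd, cutoff):
    """Independent reference implementation of the neighbor-count
    clustering (plain loops, no shared code path)."""
    m = rmsd.shape[0]
    alive = set(range(m))
    assignment = {}
    clusters = []
    while alive:
        best, best_count = None, -1
        for i in sorted(alive):
            count = sum(1 for j in alive if j != i and rmsd[i, j] < cutoff)
            if count > best_count:
                best, best_count = i, count
        members = {j for j in alive if rmsd[best, j] < cutoff} | {best}
        for j in members:
            assignment[j] = len(clusters)
        clusters.append((best, sorted(members)))
        alive -= members
    return assignment, clusters


@pytest.fixture(scope="module")
def bound_records(small_membrane):
    _, topology, frames, _ = small_membrane
    return topology, extract_dimers(frames, topology, stride=4)


class TestExtractDimers:
    def test_com_threshold_inclusive(self, c2_dimer):
        topology, _ = c2_dimer
        for sep, kept in ((5.2, True), (5.4, False)):
            topo, frames = make_c2_dimer_frames(separation=sep, spin=0.0)
            # COM distance equals the center separation by construction
            recs = extract_dimers(frames, topo, com_cutoff=5.3)
            assert bool(recs) is kept
            if recs:
                assert np.isclose(recs[0].com_distance, sep, atol=1e-9)

    def test_matches_all_pairs_loop(self, small_membrane):
        from dimerscope.geometry import center_of_mass, minimum_image, \
            unwrap_group

        _, topology, frames, _ = small_membrane
        recs = extract_dimers(frames[::40], topology, com_cutoff=5.3)
        expected = []
        for k, fr in enumerate(frames[::40]):
            coms = []
            for i in range(topology.n_proteins):
                c = fr.coords[topology.protein_slice(i)]
                c = unwrap_group(c, fr.box, c[0])
                coms.append(center_of_mass(c[topology.proteins[i].bb_indices()]))
            for i in range(topology.n_proteins):
                for j in range(i + 1, topology.n_proteins):
                    d = np.linalg.norm(minimum_image(coms[j], coms[i], fr.box))
                    if d <= 5.3:
                        expected.append((k, (i, j)))
        assert [(r.frame_index, r.pair) for r in recs] == expected

    def test_protomer_b_is_whole_and_near_a(self, bound_records):
        topology, recs = bound_records
        for r in recs[:10]:
            com_a = r.coords_a[topology.proteins[0].bb_indices()].mean(axis=0)
            com_b = r.coords_b[topology.proteins[1].bb_indices()].mean(axis=0)
            assert np.isclose(np.linalg.norm(com_a - com_b), r.com_distance,
                              atol=1e-9)

    def test_stride(self, small_membrane):
        _, topology, frames, _ = small_membrane
        all_recs = extract_dimers(frames, topology)
        strided = extract_dimers(frames, topology, stride=10)
        assert {r.frame_index for r in strided} <= \
            {r.frame_index for r in all_recs}
        assert all(r.frame_index % 10 == 0 for r in strided)


class TestSymmetrize:
    def test_count_doubles_with_swap_flags(self, bound_records):
        _, recs = bound_records
        sym = symmetrize(recs[:10])
        assert len(sym) == 20
        assert sum(r.swapped for r in sym) == 10
        np.testing.assert_array_equal(sym[0].coords_a, sym[10].coords_b)

    def test_double_symmetrize_quadruples(self, bound_records):
        _, recs = bound_records
        assert len(symmetrize(symmetrize(recs[:5]))) == 20

    def test_c2_record_equals_its_swap_after_superposition(self, c2_dimer):
        topology, frames = c2_dimer
        rec = extract_dimers(frames, topology, com_cutoff=10.0)[0]
        sw = rec.swap()
        x = np.vstack([rec.coords_a, rec.coords_b])
        y = np.vstack([sw.coords_a, sw.coords_b])
        assert kabsch(x, y).rmsd < 1e-9


class TestGromosCluster:
    def test_identical_records_form_one_full_cluster(self, bound_records):
        topology, recs = bound_records
        copies = [recs[0]] * 7
        res = gromos_cluster(copies, topology)
        assert len(res.clusters) == 1
        assert res.clusters[0].size_pct == 100.0

    def test_two_groups_by_construction(self, bound_records):
        topology, recs = bound_records
        rmsd = np.array([[0.0, 0.3, 2.0],
                         [0.3, 0.0, 2.0],
                         [2.0, 2.0, 0.0]])
        res = gromos_cluster(recs[:3], topology, rmsd_matrix=rmsd)
        assert sorted(len(c.members) for c in res.clusters) == [1, 2]

    def test_matches_naive_reference(self, bound_records):
        topology, recs = bound_records
        sym = symmetrize(recs)[:50]
        rmsd = pairwise_rmsd_matrix(sym, topology)
        res = gromos_cluster(sym, topology, rmsd_matrix=rmsd)
        ref_assign, ref_clusters = naive_gromos(rmsd, 0.4)
        assert [c.central for c in res.clusters] == \
            [c[0] for c in ref_clusters]
        for idx in range(len(sym)):
            assert res.assignment[idx] == ref_assign[idx]

    def test_sizes_sum_to_100(self, bound_records):
        topology, recs = bound_records
        res = gromos_cluster(symmetrize(recs[:20]), topology)
        assert np.isclose(res.sizes.sum(), 100.0)
        # every record in exactly one cluster
        counts = np.bincount(res.assignment)
        assert counts.sum() == 40

    def test_central_member_has_max_neighbor_count(self, bound_records):
        topology, recs = bound_records
        sym = symmetrize(recs)[:40]
        rmsd = pairwise_rmsd_matrix(sym, topology)
        res = gromos_cluster(sym, topology, rmsd_matrix=rmsd)
        top = res.clusters[0]
        neigh = (rmsd[top.central] < 0.4).sum() - 1
        for i in range(len(sym)):
            assert (rmsd[i] < 0.4).sum() - 1 <= neigh

    def test_invalid_cutoff(self, bound_records):
        topology, recs = bound_records
        with pytest.raises(ValueError):
            gromos_cluster(recs[:2], topology, rmsd_cutoff=0.0)


class TestSymmetryPairs:
    def test_c2_population_gives_self_paired_cluster(self, c2_dimer):
        topology, _ = c2_dimer
        _, frames = make_c2_dimer_frames(spin=0.7, n_frames=8, jitter=0.02,
                                         seed=4)
        recs = extract_dimers(frames, topology, com_cutoff=10.0)
        sym = symmetrize(recs)
        res = gromos_cluster(sym, topology)
        pairs, self_sym = symmetry_pairs(res, sym, topology)
        assert res.clusters[0].cluster_id in self_sym

    def test_asymmetric_population_gives_mutual_pair_of_equal_size(self):
        # an asymmetric dimer: B rotated by a non-trivial spin relative to
        # the C2 arrangement, so record != its swap
        topo, frames = make_c2_dimer_frames(spin=0.9, n_frames=6,
                                            jitter=0.02, seed=9)
        base = extract_dimers(frames, topo, com_cutoff=10.0)
        # break the symmetry: spin protomer B by 60 degrees in place
        rot = np.array([[0.5, -np.sqrt(3) / 2, 0],
                        [np.sqrt(3) / 2, 0.5, 0],
                        [0, 0, 1.0]])
        for r in base:
            center = r.coords_b.mean(axis=0)
            r.coords_b = (r.coords_b - center) @ rot.T + center
        sym = symmetrize(base)
        res = gromos_cluster(sym, topo)
        pairs, self_sym = symmetry_pairs(res, sym, topo)
        assert pairs, "expected mutually paired clusters"
        for a, b in pairs:
            na = len(res.clusters[a].members)
            nb = len(res.clusters[b].members)
            assert abs(na - nb) <= 1

    def test_pairing_matches_exhaustive_rmsd_check(self, bound_records):
        topology, recs = bound_records
        sym = symmetrize(recs[:15])
        res = gromos_cluster(sym, topology)
        pairs, self_sym = symmetry_pairs(res, sym, topology)
        from dimerscope.cluster import _fit_coords

        expected_pairs = []
        cents = {c.cluster_id: sym[c.central] for c in res.clusters}
        for i in sorted(cents):
            for j in sorted(cents):
                if i >= j:
                    continue
                r = kabsch(_fit_coords(cents[j], topology),
                           _fit_coords(cents[i].swap(), topology)).rmsd
                if r < res.rmsd_cutoff:
                    expected_pairs.append((i, j))
        assert pairs == expected_pairs


class TestInvariance:
    def test_populations_invariant_under_protein_relabeling(
            self, small_membrane):
        _, topology, frames, _ = small_membrane
        # relabel: swap protein 0 and 1 in every frame
        n = topology.proteins[0].n_beads
        swapped = [
            Frame(time=f.time, box=f.box.copy(),
                  coords=np.vstack([f.coords[n:], f.coords[:n]]))
            for f in frames
        ]
        res1 = gromos_cluster(symmetrize(extract_dimers(frames, topology,
                                                        stride=10)), topology)
        res2 = gromos_cluster(symmetrize(extract_dimers(swapped, topology,
                                                        stride=10)), topology)
        assert sorted(res1.sizes.round(6)) == sorted(res2.sizes.round(6))

    def test_order_independence_without_problematic_ties(self, bound_records):
        # constructed instance: a clique, a chain and isolated records,
        # whose greedy rounds either have a unique center or tie only
        # among records that absorb the identical member set — the cases
        # where the documented lowest-index tie-break cannot change the
        # cluster size distribution
        topology, recs = bound_records
        pos = np.array([0.0, 0.35, 0.7, 2.0, 2.1, 2.2, 2.3, 5.0, 5.1, 8.0])
        rmsd = np.abs(pos[:, None] - pos[None, :])
        sym = symmetrize(recs)[:pos.size]
        res = gromos_cluster(sym, topology, rmsd_matrix=rmsd)
        assert sorted(len(c.members) for c in res.clusters) == [1, 2, 3, 4]
        for perm_seed in range(5):
            perm = np.random.default_rng(perm_seed).permutation(pos.size)
            res_p = gromos_cluster([sym[i] for i in perm], topology,
                                   rmsd_matrix=rmsd[np.ix_(perm, perm)])
            assert sorted(len(c.members) for c in res_p.clusters) == \
                [1, 2, 3, 4]


class TestNameInterface:
    def test_designed_symmetric_interface(self, small_membrane):
        _, topology, frames, _ = small_membrane
        recs = extract_dimers(frames[-5:], topology)
        assert recs
        labels = {name_interface(r, topology) for r in recs}
        assert "TM9/TM9" in labels

    def test_multi_helix_label_format(self):
        # protomer B pushed close enough that flanking helices touch too
        topo, frames = make_c2_dimer_frames(
            separation=2 * 2.0 + 0.4, spin=-2 * np.pi * 8 / 12)
        rec = extract_dimers(frames, topo, com_cutoff=10.0)[0]
        label = name_interface(rec, topo)
        a, b = label.split("/")
        assert "TM9" in a.split(",") and "TM9" in b.split(",")
        nums = [int(h[2:]) for h in a.split(",")]
        assert nums == sorted(nums)

    def test_distant_protomers_labeled_none(self):
        topo, frames = make_c2_dimer_frames(separation=7.5, spin=0.2)
        rec = extract_dimers(frames, topo, com_cutoff=10.0)[0]
        assert name_interface(rec, topo) == "none"
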