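"""Transmission phasing and IBD inference: forced deductions, planted-crossover
recovery, an exhaustive minimal-recombination oracle, and truth replay on the
synthetic family."""

import itertools

import numpy as np
import pytest

from famprior.ibd import (
    MarkerGenotypes,
    MendelianError,
    TransmissionTrack,
    _ChromTrack,
    _phase_one_parent,
    ibd2_regions,
    ibd_states,
    phase_nuclear_family,
    select_candidate_regions,
    sib_ibd_state_fractions,
)
from famprior.intervals import RegionSet
from famprior.pedigree import Pedigree, PedigreeMember


def _family(n_children, affected=()):
    members = [
        PedigreeMember("F", None, None, 1, False),
        PedigreeMember("M", None, None, 2, False),
    ]
    for i in range(n_children):
        cid = f"c{i}"
        members.append(PedigreeMember(cid, "F", "M", 0, cid in affected))
    return Pedigree("T", members)


def _markers(father_gts, mother_gts, child_gts, chrom="chr1", spacing=1000):
    """Build MarkerGenotypes from per-marker allele-pair lists."""
    out = []
    n = len(father_gts)
    for i in range(n):
        gts = {"F": father_gts[i], "M": mother_gts[i]}
        for cid, gl in child_gts.items():
            gts[cid] = gl[i]
        out.append(MarkerGenotypes(f"m{i}", chrom, (i + 1) * spacing, gts))
    return out


class TestPhasing:
    def test_forced_deduction_from_hom_other_parent(self):
        # father A/B, mother A/A, child A/B: the B must come from the father,
        # and hapA is anchored to allele A, so the child's paternal origin is hapB.
        markers = _markers([("A", "B")], [("A", "A")], {"c0": [("A", "B")]})
        ped = _family(1)
        track = phase_nuclear_family(markers, ped)
        assert track.origin("chr1", "c0", "father")[0] == 1
        assert track.origin("chr1", "c0", "mother")[0] == -1  # mother uninformative

    def test_planted_crossover_recovered(self):
        # fully informative: father A/B everywhere (hap0=A, hap1=B), mother A/A.
        n = 10
        truth = {
            "c0": [0] * n,
            "c1": [1] * n,
            "c2": [0] * 5 + [1] * 5,  # one crossover after marker 5
            "c3": [1] * n,
        }
        child_gts = {
            c: [("A" if o == 0 else "B", "A") for o in orig] for c, orig in truth.items()
        }
        markers = _markers([("A", "B")] * n, [("A", "A")] * n, child_gts)
        track = phase_nuclear_family(markers, _family(4))
        for c, orig in truth.items():
            assert track.origin("chr1", c, "father").tolist() == orig

    def test_mendelian_violation_names_marker_and_child(self):
        markers = _markers([("A", "A")], [("A", "A")], {"c0": [("B", "B")]})
        with pytest.raises(MendelianError, match="m0.*c0"):
            phase_nuclear_family(markers, _family(1))

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        """Wherever the minimal-recombination phase assignment is unique, the
        dynamic program must return it (checked against brute force over all
        per-marker phase flips on <= 12 markers)."""
        rng = np.random.default_rng(seed)
        n, kids = 10, ["c0", "c1", "c2"]
        f_haps = rng.integers(0, 2, size=(2, n))
        m_haps = rng.integers(0, 2, size=(2, n))
        t_f = {c: _random_origins(n, rng) for c in kids}
        t_m = {c: _random_origins(n, rng) for c in kids}
        al = lambda x: "AB"[int(x)]
        child_gts = {
            c: [
                (al(f_haps[t_f[c][i], i]), al(m_haps[t_m[c][i], i]))
                for i in range(n)
            ]
            for c in kids
        }
        father_gts = [(al(f_haps[0, i]), al(f_haps[1, i])) for i in range(n)]
        mother_gts = [(al(m_haps[0, i]), al(m_haps[1, i])) for i in range(n)]
        markers = _markers(father_gts, mother_gts, child_gts)

        got = _phase_one_parent(markers, "F", "M", kids)

        # independent deduction of transmitted-allele bits per marker
        bits = []
        for i, m in enumerate(markers):
            gf = m.genotypes["F"]
            if gf[0] == gf[1]:
                continue
            x, y = sorted(gf)
            row = {}
            for c in kids:
                a, b = m.genotypes[c]
                gm = m.genotypes["M"]
                opts = set()
                for t, rest in ((a, b), (b, a)):
                    if t in (x, y) and rest in gm:
                        opts.add(t)
                if len(opts) == 1:
                    row[c] = 0 if opts.pop() == x else 1
            if row:
                bits.append((i, row))
        if not bits:
            return

        best_cost, best_solutions = None, []
        for flips in itertools.product(*([(0,)] + [(0, 1)] * (len(bits) - 1))):
            cost = 0
            origins = {c: [] for c in kids}
            for (i, row), f in zip(bits, flips):
                for c in kids:
                    if c in row:
                        origins[c].append(row[c] ^ f)
            for c in kids:
                cost += sum(a != b for a, b in zip(origins[c], origins[c][1:]))
            if best_cost is None or cost < best_cost:
                best_cost, best_solutions = cost, [flips]
            elif cost == best_cost:
                best_solutions.append(flips)

        # the DP must achieve the optimal crossover count
        dp_cost = 0
        for c in kids:
            known = [got[c][i] for i, _ in bits if got[c][i] != -1]
            dp_cost += sum(a != b for a, b in zip(known, known[1:]))
        assert dp_cost == best_cost
        if len(best_solutions) == 1:
            flips = best_solutions[0]
            for (i, row), f in zip(bits, flips):
                for c, v in row.items():
                    assert got[c][i] == v ^ f


def _random_origins(n, rng):
    """Origin vector with 0-2 crossovers."""
    o = np.zeros(n, dtype=int) + int(rng.integers(2))
    for _ in range(int(rng.integers(3))):
        cut = int(rng.integers(1, n))
        o[cut:] ^= 1
    return o


def _toy_track(origins, positions=None, chrom="chr1"):
    """Build a TransmissionTrack from {(child, role): list} origin vectors."""
    children = sorted({c for c, _ in origins})
    n = len(next(iter(origins.values())))
    pos = np.array(positions if positions is not None else [(i + 1) * 10 for i in range(n)])
    track = TransmissionTrack(children=children)
    full = {}
    for c in children:
        for role in ("father", "mother"):
            full[(c, role)] = np.array(
                origins.get((c, role), [0] * n), dtype=np.int8
            )
    track.chroms[chrom] = _ChromTrack(pos.astype(np.int64), [f"m{i}" for i in range(n)], full)
    return track


class TestIBDStates:
    def test_state2_when_both_origins_match(self):
        track = _toy_track(
            {
                ("a", "father"): [0, 0, 0],
                ("a", "mother"): [1, 1, 1],
                ("b", "father"): [0, 0, 0],
                ("b", "mother"): [1, 1, 1],
            }
        )
        (seg,) = ibd_states(track, ("a", "b"))
        assert seg.state == 2
        assert (seg.interval.start, seg.interval.end) == (10, 30)

    def test_state1_same_maternal_only(self):
        track = _toy_track(
            {
                ("a", "father"): [0, 0],
                ("a", "mother"): [1, 1],
                ("b", "father"): [1, 1],
                ("b", "mother"): [1, 1],
            }
        )
        (seg,) = ibd_states(track, ("a", "b"))
        assert seg.state == 1

    def test_boundary_at_midpoint(self):
        track = _toy_track(
            {
                ("a", "father"): [0, 0, 0, 0],
                ("a", "mother"): [0, 0, 1, 1],
                ("b", "father"): [0, 0, 0, 0],
                ("b", "mother"): [0, 0, 0, 0],
            },
            positions=[100, 200, 300, 400],
        )
        segs = ibd_states(track, ("a", "b"))
        assert [(s.state, s.interval.start, s.interval.end) for s in segs] == [
            (2, 100, 250),
            (1, 251, 400),
        ]

    def test_symmetric_in_the_pair(self, sim):
        _, truth = sim
        track = truth.track()
        a = ibd_states(track, ("8", "10"))
        b = ibd_states(track, ("10", "8"))
        assert [(s.interval, s.state) for s in a] == [(s.interval, s.state) for s in b]

    def test_segments_tile_without_overlap(self, sim):
        _, truth = sim
        segs = ibd_states(truth.track(), ("3", "4"))
        by_chrom = {}
        for s in segs:
            by_chrom.setdefault(s.interval.chrom, []).append(s.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end < b.start  # no overlap
                assert b.start == a.end + 1  # contiguous tiling

    def test_founder_in_pair_rejected(self, sim_inputs):
        _, truth = sim_inputs["manifest"], sim_inputs["truth"]
        with pytest.raises(ValueError, match="founder"):
            ibd_states(truth.track(), ("1", "10"), ped=sim_inputs["ped"])


class TestPhasedVsTruth:
    def test_phased_ibd_matches_truth_tracks(self, sim_inputs):
        """IBD2 regions inferred from phased genotypes coincide with those from
        the simulator's true transmission vectors (boundaries differ by at most
        the inter-marker spacing)."""
        from famprior.ibd import read_genotype_table

        markers = read_genotype_table(sim_inputs["manifest"]["genotypes.tsv"])
        phased = phase_nuclear_family(markers, sim_inputs["ped"])
        truth_track = sim_inputs["truth"].track()
        total = sum(l for _, l in [("c", 20_000_000)] * 4)
        for pair in [("8", "10"), ("3", "8")]:
            got = ibd2_regions(phased, pair)
            want = ibd2_regions(truth_track, pair)
            sym_diff = got.subtract(want).total_bp() + want.subtract(got).total_bp()
            assert sym_diff < 0.05 * total


class TestCandidateRegions:
    def test_no_unaffected_siblings_returns_ibd2(self):
        origins = {
            ("p1", "father"): [0, 0, 0],
            ("p1", "mother"): [0, 0, 0],
            ("p2", "father"): [0, 0, 0],
            ("p2", "mother"): [0, 0, 1],
        }
        track = _toy_track(origins)
        ped = _family(2, affected=("c0", "c1"))
        # rename track children to match the pedigree
        track.children = ["c0", "c1"]
        ct = track.chroms["chr1"]
        ct.origins = {
            ("c0", "father"): ct.origins[("p1", "father")],
            ("c0", "mother"): ct.origins[("p1", "mother")],
            ("c1", "father"): ct.origins[("p2", "father")],
            ("c1", "mother"): ct.origins[("p2", "mother")],
        }
        got = select_candidate_regions(track, ped)
        assert got == ibd2_regions(track, ("c0", "c1"))

    def test_sibling_sharing_excludes_span(self):
        # sib shares both haplotypes with proband 1 over the first two markers
        origins = {
            ("c0", "father"): [0, 0, 0, 0],
            ("c0", "mother"): [0, 0, 0, 0],
            ("c1", "father"): [0, 0, 0, 0],
            ("c1", "mother"): [0, 0, 0, 0],
            ("c2", "father"): [0, 0, 1, 1],
            ("c2", "mother"): [0, 0, 0, 0],
        }
        track = _toy_track(origins, positions=[10, 20, 30, 40])
        ped = _family(3, affected=("c0", "c1"))
        got = select_candidate_regions(track, ped)
        # probands are IBD2 everywhere (10-40); sib c2 is IBD2 with both
        # probands over 10-25, so only 26-40 survives
        assert list(got) == list(RegionSet.from_tuples([("chr1", 26, 40)]))

    def test_requires_two_probands(self):
        track = _toy_track({("c0", "father"): [0], ("c0", "mother"): [0]})
        with pytest.raises(ValueError, match="two probands"):
            select_candidate_regions(track, _family(1))

    def test_truth_replay_set_algebra(self, sim_inputs):
        """On the true transmission tracks the selection equals explicit set
        algebra over pairwise IBD2 region sets."""
        truth = sim_inputs["truth"]
        ped = sim_inputs["ped"]
        track = truth.track()
        got = select_candidate_regions(track, ped)
        p1, p2 = ped.probands
        expected = ibd2_regions(track, (p1, p2))
        excl = RegionSet()
        for sib in ped.unaffected_children:
            for p in (p1, p2):
                excl = excl.union(ibd2_regions(track, (p, sib.member_id)))
        assert got == expected.subtract(excl)
        assert not got.subtract(expected)  # result within the proband IBD2 set


class TestExpectedIBD2:
    def test_zero_genetic_length_states(self):
        # no recombination: each draw is a whole-chromosome state drawn
        # (1/4, 1/2, 1/4); the IBD2 fraction converges to 0.25
        f = sib_ibd_state_fractions(4000, genome=[("c", 1000)], cm_per_mb=0.0, seed=5)
        se = np.sqrt(np.array([0.25 * 0.75, 0.5 * 0.5, 0.25 * 0.75]) / 4000)
        assert abs(f[0] - 0.25) < 3 * se[0]
        assert abs(f[1] - 0.50) < 3 * se[1]
        assert abs(f[2] - 0.25) < 3 * se[2]
        assert f.sum() == pytest.approx(1.0)

    def test_fraction_requires_positive_n(self):
        with pytest.raises(ValueError):
            sib_ibd_state_fractions(0)
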