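"""Single-point scan, additive estimates and top-k enumeration."""

import numpy as np
import pytest

from httscan import (
    DeltaETable,
    EnergyModelConfig,
    apply_mutation,
    build_ideal_helix,
    classify,
    enumerate_top_k,
    estimate_combination,
    minimize,
    scan_single_point,
    total_energy,
)
from httscan.landscape import (
    DESTABILIZING,
    NEUTRAL,
    STABILIZING,
    enumerate_exhaustive,
)
from httscan.peptide_model import MutationSpec, parse_mutations
from httscan.residues import CANONICAL


def random_table(rng, sequence, tie_grid=None):
    """Random landscape with zero identity cells; tie_grid coarsens values to
    force ties."""
    values = rng.normal(0, 5, size=(len(sequence), 20))
    if tie_grid:
        values = np.round(values / tie_grid) * tie_grid
    for p, aa in enumerate(sequence):
        values[p, CANONICAL.index(aa)] = 0.0
    return DeltaETable(native_sequence=sequence, values=values)


@pytest.fixture(scope="module")
def toy_scan():
    peptide = build_ideal_helix("MKA")
    return peptide, scan_single_point(peptide, max_steps=40)


class TestScan:
    def test_dimensions_and_identity_cells(self, toy_scan):
        peptide, table = toy_scan
        assert table.values.shape == (3, 20)
        for p, aa in enumerate(peptide.sequence):
            assert table.get(p + 1, aa) == 0.0

    def test_cell_matches_independent_recomputation(self, toy_scan):
        peptide, table = toy_scan
        config = EnergyModelConfig()
        native = minimize(peptide, config, max_steps=40,
                          track_solvation=False)
        e0 = total_energy(native, config).total
        mutant = apply_mutation(native, MutationSpec.parse("K2D"))
        relaxed = minimize(mutant, config, max_steps=40,
                           track_solvation=False)
        expected = total_energy(relaxed, config).total - e0
        assert table.get(2, "D") == pytest.approx(expected, abs=1e-9)

    def test_scan_order_independent(self):
        peptide = build_ideal_helix("MK")
        fwd = scan_single_point(peptide, max_steps=25, positions=[1, 2])
        rev = scan_single_point(peptide, max_steps=25, positions=[2, 1])
        assert np.array_equal(fwd.values, rev.values)

    def test_provenance_records_config_hash(self, toy_scan):
        _, table = toy_scan
        assert table.provenance == EnergyModelConfig().config_hash()


class TestEstimateCombination:
    def test_single_mutation_equals_table_entry(self, rng):
        table = random_table(rng, "MKACD")
        est = estimate_combination(table, parse_mutations("K2E"))
        assert est.delta_e_estimate == table.get(2, "E")

    def test_empty_combination_is_zero(self, rng):
        table = random_table(rng, "MKACD")
        assert estimate_combination(table, []).delta_e_estimate == 0.0

    def test_additive_over_disjoint_sets(self, rng):
        table = random_table(rng, "MKACDW")
        a = parse_mutations("M1K K2E")
        b = parse_mutations("C4D W6F")
        lhs = estimate_combination(table, a + b).delta_e_estimate
        rhs = (
            estimate_combination(table, a).delta_e_estimate
            + estimate_combination(table, b).delta_e_estimate
        )
        assert lhs == rhs  # exact, no re-evaluation of structure energies

    def test_duplicate_positions_rejected(self, rng):
        table = random_table(rng, "MKACD")
        with pytest.raises(ValueError, match="duplicate"):
            estimate_combination(table, parse_mutations("K2E K2D"))

    def test_wild_type_mismatch_rejected(self, rng):
        table = random_table(rng, "MKACD")
        with pytest.raises(ValueError, match="mismatch"):
            estimate_combination(table, parse_mutations("A2E"))


class TestEnumerateTopK:
    @pytest.mark.parametrize("n,k", [(1, 1), (1, 7), (2, 10), (3, 5)])
    def test_matches_exhaustive_enumeration(self, rng, n, k):
        for trial in range(4):
            table = random_table(rng, "MKACD")
            fast = enumerate_top_k(table, n=n, k=k)
            slow = enumerate_exhaustive(table, n=n, k=k)
            assert [
                (e.mutation_string, e.delta_e_estimate) for e in fast
            ] == [(e.mutation_string, e.delta_e_estimate) for e in slow]

    def test_matches_exhaustive_with_heavy_ties(self, rng):
        for trial in range(4):
            table = random_table(rng, "MKAC", tie_grid=4.0)
            fast = enumerate_top_k(table, n=2, k=12)
            slow = enumerate_exhaustive(table, n=2, k=12)
            assert [
                (e.mutation_string, e.delta_e_estimate) for e in fast
            ] == [(e.mutation_string, e.delta_e_estimate) for e in slow]

    def test_n1_k1_is_global_minimum(self, rng):
        table = random_table(rng, "MKACD")
        top = enumerate_top_k(table, n=1, k=1)
        assert len(top) == 1
        assert top[0].delta_e_estimate == pytest.approx(table.values.min())

    def test_allowed_set_restricts_candidates(self, rng):
        table = random_table(rng, "MKACD")
        allowed = set(parse_mutations("M1K K2E A3G C4S D5E"))
        out = enumerate_top_k(table, n=2, k=50, allowed=allowed)
        assert out == enumerate_exhaustive(table, n=2, k=50, allowed=allowed)
        legal = {(m.position, m.mutant) for m in allowed}
        for est in out:
            for m in est.mutations:
                assert (m.position, m.mutant) in legal

    def test_n_exceeding_positions_rejected(self, rng):
        table = random_table(rng, "MKA")
        with pytest.raises(ValueError, match="exceeds"):
            enumerate_top_k(table, n=4, k=1)

    def test_ranks_are_ascending(self, rng):
        table = random_table(rng, "MKACDW")
        out = enumerate_top_k(table, n=2, k=15)
        assert [e.rank for e in out] == list(range(1, 16))
        values = [e.delta_e_estimate for e in out]
        assert values == sorted(values)


class TestClassify:
    def test_sign_rule_and_identity_neutral(self, rng):
        table = random_table(rng, "MKACD")
        labels = classify(table)
        for p in range(5):
            for j, aa in enumerate(CANONICAL):
                v = table.values[p, j]
                if aa == table.native_sequence[p]:
                    assert labels[p, j] == NEUTRAL
                elif v < 0:
                    assert labels[p, j] == STABILIZING
                elif v > 0:
                    assert labels[p, j] == DESTABILIZING

    def test_partition_sums_to_cell_count(self, rng):
        table = random_table(rng, "MKACD")
        labels = classify(table, threshold=2.0)
        counts = {
            lab: int((labels == lab).sum())
            for lab in (STABILIZING, DESTABILIZING, NEUTRAL)
        }
        assert sum(counts.values()) == 5 * 20

    def test_strongly_negative_cell_is_stabilizing(self, rng):
        table = random_table(rng, "MKACD")
        table.values[0, CANONICAL.index("K")] = -668.3
        assert classify(table)[0, CANONICAL.index("K")] == STABILIZING


class TestCsvRoundTrip:
    def test_roundtrip(self, rng, tmp_path):
        table = random_table(rng, "MKACD")
        table.provenance = "deadbeef"
        path = tmp_path / "landscape.csv"
        table.to_csv(path)
        back = DeltaETable.from_csv(path)
        assert back.native_sequence == table.native_sequence
        assert back.provenance == "deadbeef"
        assert np.allclose(back.values, table.values)


class TestAdditivityOnStructure:
    def test_distant_pair_estimate_matches_direct_recomputation(self):
        # two mutations far apart along the helix: the additive estimate
        # should match a direct 2-point evaluation within max(10%, 2 kcal/mol)
        config = EnergyModelConfig()
        peptide = build_ideal_helix("MATLEKLMKAFESLKSF")
        native = minimize(peptide, config, max_steps=60, track_solvation=False)
        e0 = total_energy(native, config).total

        singles = {}
        for text in ("T3W", "L14W"):
            spec = MutationSpec.parse(text)
            relaxed = minimize(
                apply_mutation(native, spec), config, max_steps=60,
                track_solvation=False,
            )
            singles[text] = total_energy(relaxed, config).total - e0
        # sites are ~16 A apart on the helix
        ca3 = native.coords[native.atom_index(3, "CA")]
        ca14 = native.coords[native.atom_index(14, "CA")]
        assert np.linalg.norm(ca3 - ca14) >= 10.0

        double = apply_mutation(
            apply_mutation(native, MutationSpec.parse("T3W")),
            MutationSpec.parse("L14W"),
        )
        relaxed = minimize(double, config, max_steps=60, track_solvation=False)
        direct = total_energy(relaxed, config).total - e0
        additive = singles["T3W"] + singles["L14W"]
        tol = max(0.1 * abs(direct), 2.0)
        assert abs(direct - additive) <= tol
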