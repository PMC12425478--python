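"""Structural attributes: SASA quadrature vs analytic spheres, geometry,
composition, interface contacts vs brute-force scans, the linear affinity
model, contact networks, and Gaussian-network-model spectra."""

import itertools

import numpy as np
import pytest
import scipy.linalg

from helpers import ca_structure, helix_structure, make_residue, single_atom_structure, two_chain_complex
from nitroscape.core_io import Chain, Structure
from nitroscape.struct_attributes import (
    InterfaceContactCounts,
    NISComposition,
    PRODIGY_COEFFICIENTS,
    affinity_score,
    attribute_table,
    charged_fraction,
    contact_network_counts,
    gnm_modes,
    interface_contacts,
    interface_residues,
    kirchhoff_matrix,
    nis_composition,
    radius_of_gyration,
    residue_class,
    sasa,
)

# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def test_sasa_isolated_carbon_matches_analytic_sphere():
    s = single_atom_structure("C")
    _, total = sasa(s)
    analytic = 4.0 * np.pi * (1.7 + 1.4) ** 2
    assert total == pytest.approx(analytic, rel=0.02)


def test_sasa_two_distant_atoms_additive():
    res_a = make_residue("ALA", 1, "A", [("CA", "C", (0.0, 0.0, 0.0))])
    res_b = make_residue("ALA", 2, "A", [("CA", "C", (100.0, 0.0, 0.0))], serial_start=2)
    s = Structure(id="two", chains=[Chain(id="A", residues=[res_a, res_b])])
    _, total = sasa(s)
    _, single = sasa(single_atom_structure("C"))
    assert total == pytest.approx(2 * single, rel=1e-9)


def test_sasa_caged_atom_nearly_buried():
    directions = [
        np.array(v, dtype=float)
        for v in itertools.product((-1, 0, 1), repeat=3)
        if any(v)
    ]
    atoms = [("CA", "C", (0.0, 0.0, 0.0))]
    for k, d in enumerate(directions):
        u = d / np.linalg.norm(d)
        atoms.append((f"C{k}", "C", tuple(2.0 * u)))
    res = make_residue("ALA", 1, "A", atoms)
    s = Structure(id="cage", chains=[Chain(id="A", residues=[res])])
    # validate() would reject duplicate names; names are unique here
    areas, _ = sasa(s)
    assert areas[0] == pytest.approx(0.0, abs=1e-9)


def test_sasa_decreases_on_contact():
    def complex_at(gap):
        a = make_residue("ALA", 1, "A", [("CA", "C", (0.0, 0.0, 0.0))])
        b = make_residue("ALA", 1, "B", [("CA", "C", (gap, 0.0, 0.0))], serial_start=2)
        return Structure(id="g", chains=[Chain(id="A", residues=[a]), Chain(id="B", residues=[b])])

    _, far = sasa(complex_at(50.0))
    _, near = sasa(complex_at(4.0))
    assert near < far


def test_sasa_unknown_element_errors():
    s = single_atom_structure("XX")
    with pytest.raises(ValueError):
        sasa(s)


# ---------------------------------------------------------------------------
# Geometry and composition
# ---------------------------------------------------------------------------


def test_radius_of_gyration_cases():
    one = ca_structure("A", np.array([[3.0, 4.0, 5.0]]))
    assert radius_of_gyration(one) == pytest.approx(0.0)

    two = ca_structure("AG", np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]))
    assert radius_of_gyration(two) == pytest.approx(1.0)

    square = ca_structure(
        "AAAA",
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 1.0, 0.0]]),
    )
    assert radius_of_gyration(square) == pytest.approx(np.sqrt(0.5), abs=1e-12)


def test_charged_fraction_values():
    assert charged_fraction(["DEKR"]) == 1.0
    assert charged_fraction(["GGGG"]) == 0.0
    assert charged_fraction(["DGKG"]) == 0.5
    assert charged_fraction(["DG", "KG"]) == 0.5  # pooled over subunits


def test_charged_fraction_histidine_excluded_by_default_but_configurable():
    assert charged_fraction(["HHHH"]) == 0.0
    assert charged_fraction(["HHHH"], charged=set("DEKRH")) == 1.0


def test_charged_fraction_nonstandard_letter_excluded_with_warning():
    with pytest.warns(UserWarning):
        assert charged_fraction(["DX"]) == 1.0  # X dropped from both counts


def test_residue_classes():
    assert residue_class("K") == "charged"
    assert residue_class("H") == "charged"
    assert residue_class("L") == "apolar"
    assert residue_class("S") == "polar"


# ---------------------------------------------------------------------------
# Interfaces and affinity
# ---------------------------------------------------------------------------


def test_interface_no_contact_beyond_cutoff():
    s = two_chain_complex(separation=6.0)
    icc = interface_contacts(s, ["D"], ["K"], cutoff=5.5)
    assert icc.total == 0


def test_interface_single_charged_charged_contact():
    s = two_chain_complex(separation=4.0)
    icc = interface_contacts(s, ["D"], ["K"], cutoff=5.5)
    assert (icc.cc, icc.total) == (1, 1)


def test_interface_symmetric_in_groups():
    s = two_chain_complex(separation=4.0)
    a = interface_contacts(s, ["D"], ["K"])
    b = interface_contacts(s, ["K"], ["D"])
    assert (a.cc, a.cp, a.ca, a.pp, a.pa, a.aa) == (b.cc, b.cp, b.ca, b.pp, b.pa, b.aa)


def test_interface_group_validation():
    s = two_chain_complex()
    with pytest.raises(ValueError):
        interface_contacts(s, [], ["K"])
    with pytest.raises(ValueError):
        interface_contacts(s, ["D"], ["D"])


def _random_complex(seed, n_per_chain=8):
    rng = np.random.default_rng(seed)
    names = ["LYS", "ASP", "SER", "LEU", "GLY", "THR", "ARG", "PHE"]
    chains = []
    serial = 1
    for cid, offset in (("D", 0.0), ("K", 5.0)):
        residues = []
        for i in range(n_per_chain):
            center = rng.uniform(0, 14, 3) + np.array([offset, 0.0, 0.0])
            atoms = [
                (f"A{k}", "C", tuple(center + rng.uniform(-0.8, 0.8, 3))) for k in range(3)
            ]
            residues.append(
                make_residue(names[i % len(names)], i + 1, cid, atoms, serial_start=serial)
            )
            serial += 3
        chains.append(Chain(id=cid, residues=residues))
    return Structure(id=f"rc{seed}", chains=chains)


def test_interface_contacts_match_brute_force_scan():
    from nitroscape.struct_attributes import THREE_TO_ONE

    for seed in range(4):
        s = _random_complex(seed)
        icc = interface_contacts(s, ["D"], ["K"], cutoff=5.5)
        # O(n²) oracle over all heavy-atom pairs
        counts = {"cc": 0, "cp": 0, "ca": 0, "pp": 0, "pa": 0, "aa": 0}
        key_map = {
            frozenset(["charged"]): "cc",
            frozenset(["charged", "polar"]): "cp",
            frozenset(["charged", "apolar"]): "ca",
            frozenset(["polar"]): "pp",
            frozenset(["polar", "apolar"]): "pa",
            frozenset(["apolar"]): "aa",
        }
        for res_a in s.chain("D").residues:
            for res_b in s.chain("K").residues:
                close = any(
                    np.linalg.norm(x.coords - y.coords) <= 5.5
                    for x in res_a.atoms
                    for y in res_b.atoms
                )
                if close:
                    pair = frozenset(
                        [
                            residue_class(THREE_TO_ONE[res_a.name]),
                            residue_class(THREE_TO_ONE[res_b.name]),
                        ]
                    )
                    counts[key_map[pair]] += 1
        assert (icc.cc, icc.cp, icc.ca, icc.pp, icc.pa, icc.aa) == tuple(
            counts[k] for k in ("cc", "cp", "ca", "pp", "pa", "aa")
        )


def test_nis_composition_of_contact_free_complex():
    # two far-apart chains: every residue is exposed, none interfacial
    def residue_at(name, index, cid, center, serial):
        return make_residue(name, index, cid, [("CA", "C", tuple(center))], serial_start=serial)

    chain_a = Chain(
        id="D",
        residues=[
            residue_at("ALA", 1, "D", (0.0, 0.0, 0.0), 1),
            residue_at("GLY", 2, "D", (10.0, 0.0, 0.0), 2),
        ],
    )
    chain_b = Chain(
        id="K",
        residues=[
            residue_at("ASP", 1, "K", (100.0, 0.0, 0.0), 3),
            residue_at("SER", 2, "K", (110.0, 0.0, 0.0), 4),
        ],
    )
    s = Structure(id="nis", chains=[chain_a, chain_b])
    nis = nis_composition(s, ["D"], ["K"])
    assert nis.percent_apolar == pytest.approx(50.0)
    assert nis.percent_charged == pytest.approx(25.0)
    assert nis.percent_polar == pytest.approx(25.0)


def test_nis_percentages_sum_invariant():
    with pytest.raises(ValueError):
        NISComposition(percent_apolar=50.0, percent_charged=30.0, percent_polar=10.0)


def test_affinity_intercept_and_linearity():
    zero = InterfaceContactCounts()
    nis0 = NISComposition(percent_apolar=0.0, percent_charged=0.0, percent_polar=100.0)
    assert affinity_score(zero, nis0) == pytest.approx(PRODIGY_COEFFICIENTS["intercept"])

    icc = InterfaceContactCounts(cc=3, ca=2, pp=1, pa=4, cp=7, aa=9)
    nis = NISComposition(percent_apolar=40.0, percent_charged=25.0, percent_polar=35.0)
    base = affinity_score(icc, nis) - PRODIGY_COEFFICIENTS["intercept"]
    icc2 = InterfaceContactCounts(cc=6, ca=4, pp=2, pa=8, cp=14, aa=18)
    nis2 = NISComposition.__new__(NISComposition)  # doubled percentages break the sum invariant
    nis2.percent_apolar, nis2.percent_charged, nis2.percent_polar = 80.0, 50.0, 70.0
    nis2.rel_sasa_cutoff = 0.05
    doubled = affinity_score(icc2, nis2) - PRODIGY_COEFFICIENTS["intercept"]
    assert doubled == pytest.approx(2 * base, abs=1e-12)


def test_affinity_matches_dot_product_oracle():
    icc = InterfaceContactCounts(cc=5, ca=3, pp=2, pa=7, cp=11, aa=13)
    nis = NISComposition(percent_apolar=41.0, percent_charged=26.0, percent_polar=33.0)
    c = PRODIGY_COEFFICIENTS
    expected = (
        c["ic_cc"] * 5 + c["ic_ca"] * 3 + c["ic_pp"] * 2 + c["ic_pa"] * 7
        + c["nis_apolar"] * 41.0 + c["nis_charged"] * 26.0 + c["intercept"]
    )
    assert affinity_score(icc, nis) == pytest.approx(expected, abs=1e-12)


def test_affinity_missing_coefficient_errors():
    icc = InterfaceContactCounts()
    nis = NISComposition(percent_apolar=0.0, percent_charged=0.0, percent_polar=100.0)
    with pytest.raises(ValueError):
        affinity_score(icc, nis, coefficients={"intercept": 0.0})


# ---------------------------------------------------------------------------
# Networks and GNM
# ---------------------------------------------------------------------------


def test_contact_network_distant_pair_no_edges():
    s = ca_structure("AG", np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]]))
    assert contact_network_counts(s)["edges"] == 0


def test_contact_network_linear_chain_excludes_bonded_neighbors():
    coords = np.column_stack([np.arange(6) * 3.8, np.zeros(6), np.zeros(6)])
    s = ca_structure("AAAAAA", coords)
    out = contact_network_counts(s, cutoff=6.5)
    assert out == {"nodes": 6, "edges": 0, "mean_degree": 0.0}


def test_contact_network_matches_brute_force_scan():
    rng = np.random.default_rng(6)
    coords = rng.uniform(0, 15, (12, 3))
    s = ca_structure("A" * 12, coords)
    out = contact_network_counts(s, cutoff=6.5)
    brute = sum(
        1
        for i in range(12)
        for j in range(i + 1, 12)
        if abs(i - j) >= 2 and np.linalg.norm(coords[i] - coords[j]) <= 6.5
    )
    assert out["edges"] == brute


def test_gnm_three_node_path_spectrum():
    coords = np.column_stack([np.arange(3) * 7.0, np.zeros(3), np.zeros(3)])
    s = ca_structure("AAA", coords)
    eigvals, fluct = gnm_modes(s, cutoff=7.5)
    np.testing.assert_allclose(sorted(eigvals), [0.0, 1.0, 3.0], atol=1e-12)
    assert len(fluct) == 3


def test_gnm_eigenvalue_sum_equals_kirchhoff_trace():
    s = helix_structure(40)
    K = kirchhoff_matrix(s)
    eigvals, _ = gnm_modes(s)
    assert eigvals.sum() == pytest.approx(np.trace(K), abs=1e-9)


def test_gnm_exactly_one_zero_mode_when_connected():
    s = helix_structure(30)
    eigvals, _ = gnm_modes(s)
    assert int(np.sum(np.abs(eigvals) < 1e-9)) == 1


def test_gnm_disconnected_graph_error_names_components():
    coords = np.vstack(
        [
            np.column_stack([np.arange(4) * 3.8, np.zeros(4), np.zeros(4)]),
            np.column_stack([np.arange(4) * 3.8 + 100.0, np.zeros(4), np.zeros(4)]),
        ]
    )
    s = ca_structure("A" * 8, coords)
    with pytest.raises(ValueError, match="2 components"):
        gnm_modes(s)


def test_gnm_matches_independent_eigensolver():
    rng = np.random.default_rng(2)
    coords = rng.uniform(0, 10, (5, 3))
    s = ca_structure("AAAAA", coords)
    K_oracle = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            if i != j and np.linalg.norm(coords[i] - coords[j]) <= 7.5:
                K_oracle[i, j] = -1.0
    np.fill_diagonal(K_oracle, -K_oracle.sum(axis=1))
    np.testing.assert_allclose(kirchhoff_matrix(s), K_oracle)
    if np.sum(np.abs(scipy.linalg.eigvalsh(K_oracle)) < 1e-9) == 1:
        eigvals, _ = gnm_modes(s)
        np.testing.assert_allclose(eigvals, scipy.linalg.eigvalsh(K_oracle), atol=1e-9)


# ---------------------------------------------------------------------------
# Attribute tables
# ---------------------------------------------------------------------------


def test_attribute_table_records_and_determinism(tmp_path):
    s1 = helix_structure(25, "s1")
    s2 = helix_structure(25, "s2")
    table = attribute_table([s1, s2])
    assert list(table.index) == ["s1", "s2"]
    core = ["total_sasa", "radius_of_gyration", "charged_fraction", "mean_slow_mode_fluctuation"]
    assert table[core].notna().all().all()
    # identical structures → identical records
    assert table.loc["s1", core].tolist() == pytest.approx(table.loc["s2", core].tolist())
    # serializes to TSV and round-trips
    import pandas as pd

    p = tmp_path / "attr.tsv"
    table.to_csv(p, sep="\t")
    back = pd.read_csv(p, sep="\t", index_col=0)
    np.testing.assert_allclose(back[core].to_numpy(dtype=float), table[core].to_numpy(dtype=float))


def test_attribute_table_failure_recorded_as_missing():
    good = helix_structure(25, "good")
    # disconnected contact graph → GNM fails, other attributes still fill in
    bad = ca_structure("AG", np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]]))
    bad.id = "bad"
    table = attribute_table([good, bad])
    assert np.isnan(table.loc["bad", "mean_slow_mode_fluctuation"])
    assert not np.isnan(table.loc["good", "mean_slow_mode_fluctuation"])
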