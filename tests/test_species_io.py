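"""Species table reading, reaction balance checking, result tables."""

import io
import json

import pytest

from metallokin import (
    Reaction,
    build_scheme_reaction,
    formation_constant,
    read_reactions,
    read_species_table,
    validate_reaction,
    write_results_table,
)
from metallokin.constants import HARTREE_TO_KCAL
from metallokin.errors import (
    DuplicateLabelError,
    SchemaError,
    SpeciesLookupError,
    TableParseError,
)
from metallokin.species_io import read_results_table
from metallokin.thermo import FormationResult

from conftest import scheme_species

HEADER = "label,role,charge,unpaired_electrons,g_standard"


class TestReadSpeciesTable:
    def test_zero_hartree_maps_to_zero_kcal(self):
        csv = f"{HEADER}\nA,ligand,-1,0,0.0\nB,water,0,0,0.0\n"
        recs = read_species_table(io.StringIO(csv), energy_unit="hartree")
        assert recs["A"].g_standard == 0.0
        assert recs["B"].g_standard == 0.0

    def test_hartree_conversion_uses_codata_factor(self):
        csv = f"{HEADER}\nA,ligand,-1,0,-1.0\n"
        recs = read_species_table(io.StringIO(csv), energy_unit="hartree")
        assert recs["A"].g_standard == pytest.approx(-HARTREE_TO_KCAL, rel=1e-15)
        assert recs["A"].g_standard == pytest.approx(-627.5094740631, rel=1e-12)

    def test_kcal_input_passes_through_unchanged(self):
        csv = f"{HEADER}\nA,ligand,-1,0,-123.456\n"
        recs = read_species_table(io.StringIO(csv))
        assert recs["A"].g_standard == -123.456

    def test_duplicate_label_rejected(self):
        csv = f"{HEADER}\n{{A1}},ligand,-1,0,0.0\n{{A1}},ligand,-1,0,1.0\n"
        with pytest.raises(DuplicateLabelError, match="A1"):
            read_species_table(io.StringIO(csv))

    def test_missing_column_names_the_column(self):
        csv = "label,role,charge,g_standard\nA,ligand,-1,0.0\n"
        with pytest.raises(SchemaError, match="unpaired_electrons"):
            read_species_table(io.StringIO(csv))

    def test_non_numeric_energy_reports_row(self):
        csv = f"{HEADER}\nA,ligand,-1,0,-3.0\nB,water,0,0,oops\n"
        with pytest.raises(TableParseError, match="row 1"):
            read_species_table(io.StringIO(csv))

    def test_tsv_and_json_inputs_agree(self):
        tsv = HEADER.replace(",", "\t") + "\nA\tligand\t-1\t0\t-3.5\n"
        js = json.dumps(
            [{"label": "A", "role": "ligand", "charge": -1,
              "unpaired_electrons": 0, "g_standard": -3.5}]
        )
        rec_tsv = read_species_table(io.StringIO(tsv))["A"]
        rec_json = read_species_table(io.StringIO(js))["A"]
        assert rec_tsv == rec_json

    def test_missing_optional_columns_stay_absent(self):
        csv = f"{HEADER}\nA,ligand,-1,0,-3.5\n"
        rec = read_species_table(io.StringIO(csv))["A"]
        assert rec.h_standard is None
        assert rec.s2_after is None
        assert rec.stokes_radius is None


class TestValidateReaction:
    @pytest.mark.parametrize("scheme", ["5", "6", "7", "8", "9", "10", "17", "18", "19", "20"])
    @pytest.mark.parametrize("x", [1, 2, 3])
    def test_all_scheme_templates_balance(self, scheme, x):
        species = scheme_species(scheme, x)
        rxn = build_scheme_reaction(scheme, x, n=0, ligand_label="L", complex_label="MLx")
        report = validate_reaction(rxn, species)
        assert report.passed, report.messages
        assert report.charge_discrepancy == 0

    @pytest.mark.parametrize("scheme,x", [("7", 2), ("18", 2), ("9", 1), ("19", 3)])
    def test_single_coefficient_perturbation_fails(self, scheme, x):
        species = scheme_species(scheme, x)
        base = build_scheme_reaction(scheme, x, n=0, ligand_label="L", complex_label="MLx")
        for side_name in ("reactants", "products"):
            side = list(getattr(base, side_name))
            for i in range(len(side)):
                perturbed = [list(t) for t in side]
                perturbed[i][1] += 1
                kwargs = {
                    "reactants": base.reactants,
                    "products": base.products,
                    "scheme_id": base.scheme_id,
                    "x": base.x,
                    "n": base.n,
                }
                kwargs[side_name] = tuple(tuple(t) for t in perturbed)
                report = validate_reaction(Reaction(**kwargs), species)
                assert not report.passed, (side_name, i)

    def test_paper_charge_patterns(self):
        # anionic ligand, x = 2, Cu: 2*(-1) + 2 on the left; (2-2) + 0 right
        species = scheme_species("7", 2)
        rxn = build_scheme_reaction("7", 2, n=0, ligand_label="L", complex_label="MLx")
        report = validate_reaction(rxn, species)
        assert (report.charge_reactants, report.charge_products) == (0, 0)
        # doubly-protonated ligand, x = 2, Cu: 2*(+1) + 2 left; 0 + 4*(+1) right
        species = scheme_species("18", 2)
        rxn = build_scheme_reaction("18", 2, n=0, ligand_label="L", complex_label="MLx")
        report = validate_reaction(rxn, species)
        assert (report.charge_reactants, report.charge_products) == (4, 4)
        assert report.passed

    def test_identity_reaction_passes_with_zero_discrepancy(self):
        species = scheme_species("7", 1)
        rxn = Reaction(reactants=(("L", 1),), products=(("L", 1),))
        report = validate_reaction(rxn, species)
        assert report.passed
        assert report.charge_discrepancy == 0

    def test_unresolvable_label_raises(self):
        species = scheme_species("7", 1)
        rxn = Reaction(reactants=(("nope", 1),), products=(("L", 1),))
        with pytest.raises(SpeciesLookupError, match="nope"):
            validate_reaction(rxn, species)

    def test_nonpositive_coefficient_rejected(self):
        with pytest.raises(ValueError):
            Reaction(reactants=(("A", 0),), products=(("A", 1),))


def _formation_result(dgf=-20.7, label="X"):
    kf, logkf = formation_constant(dgf)
    return FormationResult(
        reaction=Reaction(reactants=(("L", 1),), products=(("C", 1),), x=1, n=0),
        delta_g_raw=dgf,
        ss_correction=0.0,
        dep_penalty_total=0.0,
        delta_g_formation=dgf,
        Kf=kf,
        logKf=logkf,
        label=label,
    )


class TestResultTables:
    def test_empty_results_give_header_only(self):
        text = write_results_table([], fmt="tsv")
        assert text == "\n"
        assert json.loads(write_results_table([], fmt="json")) == []

    def test_publication_rounding(self):
        text = write_results_table([_formation_result(-20.7)], fmt="tsv")
        row = text.splitlines()[1].split("\t")
        header = text.splitlines()[0].split("\t")
        assert row[header.index("delta_g_formation")] == "-20.7"
        logkf_txt = row[header.index("logKf")]
        assert logkf_txt == "15.17"  # exactly two decimals

    def test_json_round_trip_is_lossless(self, tmp_path):
        results = [_formation_result(-20.7, "a"), _formation_result(-51.1, "b")]
        path = tmp_path / "results.json"
        write_results_table(results, fmt="json", destination=path)
        assert read_results_table(path) == results

    def test_reactions_json_round_trip(self, tmp_path):
        rxn = build_scheme_reaction("7", 2, n=0, ligand_label="L", complex_label="MLx")
        path = tmp_path / "rxn.json"
        path.write_text(json.dumps([
            {"reactants": [list(t) for t in rxn.reactants],
             "products": [list(t) for t in rxn.products],
             "scheme_id": rxn.scheme_id, "x": rxn.x, "n": rxn.n}
        ]))
        assert read_reactions(path) == [rxn]
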