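"""The six VDss methods: frozen worked examples, algebraic collapses,
and equivalence with the independent brute-force oracle."""
import dataclasses
import warnings

import pytest

from vdsspred import DrugGenSpec, generate_drugs
from vdsspred.datamodel import DrugRecord
from vdsspred.methods import (
    MethodInput,
    predict,
    vdss_adjusted_fup,
    vdss_korzekwa_nagar,
    vdss_oie_tozer,
    vdss_rr_muscle_only,
    vdss_rr_tissue_specific,
    vdss_tcm_new,
)

from _oracle import (
    oracle_adjusted_fup,
    oracle_korzekwa_nagar,
    oracle_oie_tozer,
    oracle_rr_muscle,
    oracle_rr_tissue,
    oracle_tcm_new,
)


class TestOieTozer:
    @pytest.mark.parametrize(
        "drug_name, logp, expected_L",
        [
            ("griseofulvin", 3.566, 148.349560420188),
            ("itraconazole", 6.888, 505.5662135972727),
        ],
    )
    def test_frozen_examples(self, drugs, drug_name, logp, expected_L):
        result = vdss_oie_tozer(MethodInput(drugs[drug_name], logp))
        assert result.vdss == pytest.approx(expected_L, rel=1e-9)
        assert "fut" in result.intermediates

    def test_unit_tissue_binding_ratio_identity(self, drugs):
        # when fut happens to equal fup the last term is exactly V_r
        result = vdss_oie_tozer(MethodInput(drugs["griseofulvin"], 3.566))
        fut = result.intermediates["fut"]
        fup = drugs["griseofulvin"].fup
        per_kg = result.vdss / 70.0
        assert per_kg == pytest.approx(
            0.0436 + 0.151 * fup + 1.4 * 0.0436 * (1 - fup) + 0.38 * fup / fut,
            rel=1e-12,
        )


class TestRodgersRowland:
    def test_tissue_specific_griseofulvin_low_logp(self, drugs, tissues):
        result = vdss_rr_tissue_specific(
            MethodInput(drugs["griseofulvin"], 2.511), tissues
        )
        assert result.vdss == pytest.approx(535.2469167161904, rel=1e-9)
        assert set(result.intermediates["kpu"]) == {t.tissue for t in tissues}

    def test_vdss_is_exactly_fup_times_vuss(self, drugs, tissues):
        for name, drug in drugs.items():
            for method in (vdss_rr_tissue_specific, vdss_rr_muscle_only):
                result = method(MethodInput(drug, 5.0), tissues)
                assert result.vdss == pytest.approx(
                    drug.fup * result.intermediates["vuss"], rel=1e-12
                )

    @pytest.mark.parametrize(
        "drug_name, logp, expected_L, fold",
        [
            ("itraconazole", 4.893, 132.99698106526864, 0.17),
            ("itraconazole", 6.888, 12377.158147870463, 15.47),
            ("posaconazole", 5.36, 3674.5646299674618, 12.50),
        ],
    )
    def test_muscle_only_worked_examples(
        self, drugs, tissues, observed, drug_name, logp, expected_L, fold
    ):
        result = vdss_rr_muscle_only(MethodInput(drugs[drug_name], logp), tissues)
        assert result.vdss == pytest.approx(expected_L, rel=1e-9)
        assert round(result.vdss / observed[drug_name], 2) == fold

    def test_tissue_specific_overpredicts_posaconazole(self, drugs, tissues):
        result = vdss_rr_tissue_specific(
            MethodInput(drugs["posaconazole"], 5.36), tissues
        )
        assert result.vdss > 2 * 294.0  # far above observed

    def test_oil_adipose_lowers_the_tissue_sum(self, drugs, tissues):
        octanol = vdss_rr_tissue_specific(
            MethodInput(drugs["griseofulvin"], 3.53), tissues
        )
        oil = vdss_rr_tissue_specific(
            MethodInput(
                drugs["griseofulvin"], 3.53,
                options={"adipose_partition": "oil"},
            ),
            tissues,
        )
        assert oil.vdss < octanol.vdss


class TestAdjustedFup:
    def test_plasma_only_limit(self, tissues, constants):
        # a hydrophilic, fully unbound drug barely exceeds plasma+cell space
        drug = DrugRecord(
            name="hydro", ionization_class="neutral", fup=1.0, bpr=1.0,
            logp_by_source={"admet": -4.0},
        )
        result = vdss_adjusted_fup(MethodInput(drug, -4.0), tissues, constants)
        v_cells = 0.45 / 0.55 * 3.5
        assert result.vdss == pytest.approx(
            3.5 + v_cells + sum(
                t.volume * result.intermediates["kp"][t.tissue] for t in tissues
            ),
            rel=1e-12,
        )

    def test_itraconazole_oil_adipose_within_twofold(self, drugs, tissues, observed):
        result = vdss_adjusted_fup(
            MethodInput(
                drugs["itraconazole"], 5.66, options={"adipose_partition": "oil"}
            ),
            tissues,
        )
        fold = result.vdss / observed["itraconazole"]
        assert 0.5 <= fold <= 2.0
        assert result.vdss == pytest.approx(560.8753814658694, rel=1e-9)

    def test_adjusted_fup_never_exceeds_fup(self, drugs, tissues):
        for drug in drugs.values():
            for source, logp in drug.logp_by_source.items():
                result = vdss_adjusted_fup(MethodInput(drug, logp), tissues)
                assert result.intermediates["fup_adj"] <= drug.fup


class TestKorzekwaNagar:
    def test_unavailable_without_regression_constants(self, drugs, constants):
        drug = dataclasses.replace(drugs["griseofulvin"], dipole=5.0)
        with pytest.raises(ValueError, match="unavailable"):
            vdss_korzekwa_nagar(MethodInput(drug, 3.0), constants)

    def test_low_fup_warns(self, drugs, kn_constants):
        drug = dataclasses.replace(drugs["itraconazole"], dipole=5.0)
        with pytest.warns(RuntimeWarning, match="0.005"):
            result = vdss_korzekwa_nagar(MethodInput(drug, 5.66), kn_constants)
        assert 0.0 < result.intermediates["fum"] < 1.0

    def test_formula_identity_via_intermediates(self, drugs, kn_constants):
        drug = dataclasses.replace(drugs["griseofulvin"], dipole=5.0)
        result = vdss_korzekwa_nagar(MethodInput(drug, 2.511), kn_constants)
        fum, fup = result.intermediates["fum"], drug.fup
        assert result.vdss / 70.0 == pytest.approx(
            0.043 + 0.557 * fup + 0.557 * 0.116 * (1 - fup)
            + fup * (20.0 * (1 - fum) / fum + 0.76),
            rel=1e-12,
        )


class TestTcmNew:
    def test_itraconazole_literature_logp(self, drugs):
        result = vdss_tcm_new(MethodInput(drugs["itraconazole"], 5.66))
        assert result.vdss == pytest.approx(262.8461312772433, rel=1e-9)
        assert result.intermediates["logp_oil"] == pytest.approx(
            1.099 * 5.66 - 1.31
        )

    def test_vanishing_bpr_leaves_plasma_term(self, drugs):
        tiny = dataclasses.replace(drugs["itraconazole"], bpr=1e-12)
        result = vdss_tcm_new(MethodInput(tiny, 5.66))
        assert result.vdss == pytest.approx(70.0 * 0.04, rel=1e-6)

    def test_measured_bpr_lowers_prediction_13_percent(self, drugs):
        itra = drugs["itraconazole"]
        measured = dataclasses.replace(itra, bpr=0.58)
        for logp in itra.logp_by_source.values():
            v_admet = vdss_tcm_new(MethodInput(itra, logp)).vdss
            v_measured = vdss_tcm_new(MethodInput(measured, logp)).vdss
            assert round(100.0 * (1.0 - v_measured / v_admet)) == 13


class TestDispatch:
    def test_unknown_method_names_the_valid_ones(self, drugs):
        with pytest.raises(ValueError, match="tcm_new"):
            predict(drugs["griseofulvin"], "nope", logp=3.0)

    def test_exactly_one_logp_spec(self, drugs):
        with pytest.raises(ValueError):
            predict(drugs["griseofulvin"], "tcm_new")
        with pytest.raises(ValueError):
            predict(drugs["griseofulvin"], "tcm_new", logp=3.0, logp_source="admet")

    def test_source_lookup_and_label(self, drugs, tissues, constants):
        result = predict(
            drugs["itraconazole"], "rr_muscle", logp_source="hplc",
            tissues=tissues, constants=constants,
        )
        assert result.logp_used == 6.888
        assert result.logp_source == "hplc"

    def test_repeated_calls_are_identical(self, drugs, tissues, constants):
        a = predict(drugs["posaconazole"], "rr_tissue", logp=5.36,
                    tissues=tissues, constants=constants)
        b = predict(drugs["posaconazole"], "rr_tissue", logp=5.36,
                    tissues=tissues, constants=constants)
        assert a == b

    def test_unknown_option_rejected(self, drugs):
        with pytest.raises(ValueError, match="option"):
            MethodInput(drugs["griseofulvin"], 3.0, options={"bogus": 1})


@pytest.fixture(scope="module")
def synthetic_drugs():
    return generate_drugs(DrugGenSpec(n=100, seed=20240501))


class TestOracleEquivalence:
    """Every method agrees with the plain-transcription oracle to 1e-9
    relative on 100 seeded synthetic drugs."""

    def test_all_methods_match_oracle(
        self, synthetic_drugs, tissues, tissue_dicts, kn_constants
    ):
        constants = kn_constants
        kn_map = constants.korzekwa_nagar.fum_regression
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for drug in synthetic_drugs:
                logp = drug.logp_by_source["literature"]
                pka = drug.pka
                pairs = [
                    (
                        vdss_oie_tozer(MethodInput(drug, logp), constants).vdss,
                        oracle_oie_tozer(logp, pka, drug.fup),
                    ),
                    (
                        vdss_rr_tissue_specific(
                            MethodInput(drug, logp), tissues, constants
                        ).vdss,
                        oracle_rr_tissue(logp, pka, drug.fup, tissue_dicts),
                    ),
                    (
                        vdss_rr_muscle_only(
                            MethodInput(drug, logp), tissues, constants
                        ).vdss,
                        oracle_rr_muscle(logp, pka, drug.fup, tissue_dicts),
                    ),
                    (
                        vdss_adjusted_fup(
                            MethodInput(drug, logp), tissues, constants
                        ).vdss,
                        oracle_adjusted_fup(
                            logp, pka, drug.fup, drug.bpr, tissue_dicts
                        ),
                    ),
                    (
                        vdss_korzekwa_nagar(MethodInput(drug, logp), constants).vdss,
                        oracle_korzekwa_nagar(
                            logp, pka, drug.fup, drug.hbd, drug.hba,
                            drug.n_so, drug.n_no2, drug.dipole, kn_map,
                        ),
                    ),
                    (
                        vdss_tcm_new(MethodInput(drug, logp), constants).vdss,
                        oracle_tcm_new(logp, drug.bpr),
                    ),
                ]
                for got, want in pairs:
                    assert got == pytest.approx(want, rel=1e-9)

    def test_oil_adipose_route_matches_oracle(
        self, synthetic_drugs, tissues, tissue_dicts, constants
    ):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for drug in synthetic_drugs[:20]:
                logp = drug.logp_by_source["hplc"]
                got = vdss_rr_tissue_specific(
                    MethodInput(drug, logp, options={"adipose_partition": "oil"}),
                    tissues,
                    constants,
                ).vdss
                want = oracle_rr_tissue(
                    logp, drug.pka, drug.fup, tissue_dicts, adipose_oil=True
                )
                assert got == pytest.approx(want, rel=1e-9)
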