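"""Reaction-path assembly, descriptor tables, and free-energy diagrams."""

import io

import pandas as pd
import pytest

from cypene.energetics import Molecule, Stage, StationaryPoint
from cypene.fixtures import load_paper_fixture, reconstructed_paths
from cypene.profiles import (
    assemble_path,
    build_diagram,
    path_descriptors,
    profile_report,
    render_diagram,
    round_sig,
)


class TestAssemblePath:
    def test_complete_path_flags(self, simple_path_points):
        path = assemble_path(simple_path_points)
        assert not path.barrierless_abstraction
        assert path.barrierless_rebound  # no rebound TS exists at this level

    def test_missing_ts_is_flagged_not_an_error(self, simple_path_points):
        i, _, iii, _ = simple_path_points
        path = assemble_path([i, iii])
        assert path.barrierless_abstraction

    def test_duplicate_stage_rejected(self, simple_path_points):
        with pytest.raises(ValueError, match="duplicate stage"):
            assemble_path(simple_path_points + [simple_path_points[1]])

    def test_missing_stage_i_rejected(self, simple_path_points):
        with pytest.raises(ValueError, match="stage-I"):
            assemble_path(simple_path_points[1:])

    def test_mixed_labels_rejected(self, simple_path_points, beta_delta_label):
        from dataclasses import replace

        from cypene.energetics import Stereopath

        other = replace(beta_delta_label, stereopath=Stereopath.CIS)
        alien = StationaryPoint(label=other, stage=Stage.RADICAL, g=0.0)
        with pytest.raises(ValueError, match="mixed labels"):
            assemble_path([simple_path_points[0], alien])


class TestPathDescriptors:
    def test_hand_converted_synthetic_path(self, simple_path_points):
        desc = path_descriptors(assemble_path(simple_path_points))
        assert desc.dg_act_cor == pytest.approx(0.02 * 627.5095, abs=1e-9)  # 12.55
        assert desc.d_r_g_cor == pytest.approx(-0.01 * 627.5095, abs=1e-9)  # -6.28
        assert round(desc.dg_act_cor, 2) == 12.55
        assert round(desc.d_r_g_cor, 2) == -6.28

    def test_flat_path_gives_zero_reaction_terms(self, beta_delta_label):
        pts = [
            StationaryPoint(label=beta_delta_label, stage=s, g=-5.0,
                            e_elec=-5.0, h=-5.0, g_uncorrected=-5.0)
            for s in (Stage.REACTANT_COMPLEX, Stage.RADICAL)
        ]
        desc = path_descriptors(assemble_path(pts))
        assert desc.d_r_e == desc.d_r_h == desc.d_r_g == desc.d_r_g_cor == 0.0

    def test_missing_columns_yield_none_not_zero(self, beta_delta_label):
        pts = [
            StationaryPoint(label=beta_delta_label, stage=s, g=g)
            for s, g in [(Stage.REACTANT_COMPLEX, 0.0), (Stage.RADICAL, -0.01)]
        ]
        desc = path_descriptors(assemble_path(pts))
        assert desc.d_r_g_cor is not None
        assert desc.d_r_e is None and desc.dh_act is None

    def test_hydroxylation_energy_decomposes_over_radical_step(self):
        """hyd ΔG − Δ_rG equals the III→IV corrected-G drop on every path."""
        for molecule in (Molecule.BETA_PINENE, Molecule.ALPHA_PINENE):
            for path in reconstructed_paths(molecule):
                desc = path_descriptors(path)
                drop = (
                    path[Stage.HYDROXYLATED].g - path[Stage.RADICAL].g
                ) * 627.5095
                assert desc.hyd_d_r_g_cor - desc.d_r_g_cor == pytest.approx(
                    drop, abs=1e-9
                )


@pytest.mark.parametrize(
    "molecule, fixture",
    [
        (Molecule.BETA_PINENE, "beta_descriptors"),
        (Molecule.ALPHA_PINENE, "alpha_descriptors"),
    ],
)
class TestProfileReportAgainstPrintedTables:
    def test_report_reproduces_printed_descriptors(self, molecule, fixture):
        """The packaged stage-reconstructed paths give back every printed
        descriptor cell for both pinenes."""
        report = profile_report(reconstructed_paths(molecule))
        printed = load_paper_fixture(fixture)
        col_map = {
            "d_r_e": "dE_r", "de_act": "dE_act", "d_r_h": "dH_r",
            "dh_act": "dH_act", "d_r_g": "dG_r", "dg_act": "dG_act",
            "d_r_g_cor": "dG_r_cor", "dg_act_cor": "dG_act_cor",
            "hyd_d_r_g_cor": "hyd_dG_r_cor",
        }
        assert len(report) == len(printed)
        for _, prow in printed.iterrows():
            match = report[
                (report["site"] == prow["site"])
                & (report["stereopath"] == prow["stereopath"])
                & (report["spin"] == (prow["multiplicity"] - 1) / 2)
            ]
            assert len(match) == 1
            for src, dst in col_map.items():
                assert match.iloc[0][dst] == pytest.approx(prow[src], abs=1e-9)

    def test_transition_state_betweenness(self, molecule, fixture):
        """The abstraction TS lies above the reactant complex on every path,
        and above the radical except where the printed descriptors themselves
        put the strongly endergonic radical higher — which happens on exactly
        one path, the β-pinene alpha-site doublet."""
        exceptions = []
        for path in reconstructed_paths(molecule):
            ts, i, iii = (
                path[Stage.ABSTRACTION_TS], path[Stage.REACTANT_COMPLEX],
                path[Stage.RADICAL],
            )
            assert ts.g > i.g
            if iii.g > ts.g:
                exceptions.append(path.label)
        if molecule is Molecule.BETA_PINENE:
            assert [(l.site.value, l.multiplicity) for l in exceptions] == [("alpha", 2)]
        else:
            assert exceptions == []


class TestProfileReportContracts:
    def test_row_ordering_site_spin_stereo(self):
        report = profile_report(reconstructed_paths(Molecule.BETA_PINENE))
        keys = list(zip(report["site"], report["spin"], report["stereopath"]))
        site_rank = {"alpha": 0, "delta": 2}
        stereo_rank = {"cis": 0, "trans": 1, "none": 2}
        ranked = [(site_rank[s], sp, stereo_rank[st]) for s, sp, st in keys]
        assert ranked == sorted(ranked)

    def test_empty_cells_render_empty_in_csv(self, beta_delta_label):
        pts = [
            StationaryPoint(label=beta_delta_label, stage=s, g=g)
            for s, g in [(Stage.REACTANT_COMPLEX, 0.0), (Stage.RADICAL, -0.01)]
        ]
        report = profile_report([assemble_path(pts)])
        csv = report.to_csv(index=False)
        row = csv.splitlines()[1]
        assert ",," in row and ",0," not in row

    def test_report_round_trips_through_csv(self):
        report = profile_report(reconstructed_paths(Molecule.ALPHA_PINENE))
        back = pd.read_csv(io.StringIO(report.to_csv(index=False)))
        pd.testing.assert_frame_equal(report, back, check_exact=False, atol=1e-12)


class TestDiagram:
    def test_reference_is_most_stable_reactant_complex(self):
        """For β-pinene the global zero resolves to the alpha-site doublet
        reactant complex, the most stable coordinate-I structure."""
        diagram = build_diagram(reconstructed_paths(Molecule.BETA_PINENE))
        assert diagram.reference_label.site.value == "alpha"
        assert diagram.reference_label.multiplicity == 2

    def test_alpha_pinene_reference_is_gamma_doublet(self):
        diagram = build_diagram(reconstructed_paths(Molecule.ALPHA_PINENE))
        assert diagram.reference_label.site.value == "gamma"
        assert diagram.reference_label.multiplicity == 2

    def test_flat_path_renders_at_zero(self, beta_delta_label):
        pts = [
            StationaryPoint(label=beta_delta_label, stage=s, g=-1.0)
            for s in (Stage.REACTANT_COMPLEX, Stage.ABSTRACTION_TS,
                      Stage.RADICAL, Stage.HYDROXYLATED)
        ]
        diagram = build_diagram([assemble_path(pts)])
        assert all(v == 0.0 for _, values in diagram.series for _, v in values)

    def test_csv_and_text_carry_identical_series(self):
        paths = reconstructed_paths(Molecule.BETA_PINENE)
        csv = render_diagram(paths, "csv")
        text = render_diagram(paths, "text")
        csv_vals = [float(line.rsplit(",", 1)[1]) for line in csv.splitlines()[1:]]
        text_vals = [
            float(cell.split(":")[1])
            for line in text.splitlines()[2:]
            for cell in line.split()[1:]
        ]
        assert csv_vals == pytest.approx(text_vals, abs=5e-7)

    def test_svg_deterministic_and_well_formed(self):
        paths = reconstructed_paths(Molecule.BETA_PINENE)
        a, b = render_diagram(paths, "svg"), render_diagram(paths, "svg")
        assert a == b and a.startswith("<svg") and a.rstrip().endswith("</svg>")

    def test_reference_invariance_under_uniform_shift(self):
        paths = reconstructed_paths(Molecule.BETA_PINENE)
        shifted = []
        for p in paths:
            pts = [
                StationaryPoint(label=sp.label, stage=sp.stage, g=sp.g + 7.5)
                for sp in p.stage_points.values()
            ]
            shifted.append(assemble_path(pts))
        a, b = build_diagram(paths), build_diagram(shifted)
        for (_, va), (_, vb) in zip(a.series, b.series):
            for (_, x), (_, y) in zip(va, vb):
                assert x == pytest.approx(y, abs=1e-6)

    def test_unsupported_format_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            render_diagram(reconstructed_paths(Molecule.BETA_PINENE), "png")


def test_round_sig():
    assert round_sig(12.5495, 3) == 12.5
    assert round_sig(-0.0054321, 2) == -0.0054
    assert round_sig(0.0, 3) == 0.0
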