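"""Binding-site loading, density arithmetic, and the two screens."""

import numpy as np
import pandas as pd
import pytest

from iriseq.intervals import GenomicInterval, IntronRecord
from iriseq.rbp import (
    BindingSiteIndex,
    ScreenConfig,
    binding_density,
    load_binding_sites,
    rbp_candidate_screen,
    target_gene_screen,
)


def _record(intron_id, gene_id, start, end, fu=(0, 100), fd=None):
    fd = fd or (end + 50, end + 150)
    return IntronRecord(
        intron_id=intron_id,
        gene_id=gene_id,
        interval=GenomicInterval("chr1", start, end),
        flank_up=GenomicInterval("chr1", *fu),
        flank_down=GenomicInterval("chr1", *fd),
        index=1,
        length=end - start,
    )


class TestLoading:
    def test_groups_and_rejects(self, tmp_path, caplog):
        bed = tmp_path / "s.bed"
        bed.write_text(
            "chr1\t10\t40\tRBP_A\n"
            "chr1\t50\t80\tRBP_A\n"
            "chr1\t10\t40\tRBP_B\n"
            "chr1\t90\t90\tRBP_B\n"  # start >= end -> rejected
        )
        idx = load_binding_sites(bed)
        assert idx.rbp_names == ["RBP_A", "RBP_B"]
        assert len(idx.sites) == 3

    def test_empty_file(self, tmp_path):
        bed = tmp_path / "e.bed"
        bed.write_text("")
        assert load_binding_sites(bed).rbp_names == []

    def test_too_few_columns_errors(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t10\t40\n")
        with pytest.raises(ValueError, match="line 1"):
            load_binding_sites(bed)


class TestDensity:
    def test_sites_per_kb(self):
        sites = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [200, 600, 1000],
                "end": [230, 630, 1030],
                "rbp": ["R"] * 3,
                "source": [""] * 3,
            }
        )
        idx = BindingSiteIndex(sites=sites)
        rec = _record("i1", "g1", 150, 1650)  # 1,500 bp
        dens = binding_density(idx, [rec], rbp="R")
        assert dens.loc[0, "n_sites"] == 3
        assert dens.loc[0, "density"] == pytest.approx(2.0)

    def test_one_bp_boundary_overlap_counts(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1"], "start": [120], "end": [151],
             "rbp": ["R"], "source": [""]}
        )
        idx = BindingSiteIndex(sites=sites)
        rec = _record("i1", "g1", 150, 1650)
        assert binding_density(idx, [rec], rbp="R").loc[0, "n_sites"] == 1
        # site ending exactly at the intron start does not overlap
        idx2 = BindingSiteIndex(sites=sites.assign(end=[150]))
        assert binding_density(idx2, [rec], rbp="R").loc[0, "n_sites"] == 0

    def test_no_sites_and_permutation_invariance(self):
        idx = BindingSiteIndex(
            sites=pd.DataFrame(
                columns=["chrom", "start", "end", "rbp", "source"]
            )
        )
        recs = [_record("i1", "g1", 150, 1150), _record("i2", "g2", 2000, 3000)]
        d1 = binding_density(idx, recs)
        d2 = binding_density(idx, recs[::-1])
        assert (d1["density"] == 0).all()
        assert set(d1["intron_id"]) == set(d2["intron_id"])


def _expression_tables(rbps, drop_rbp=None, n_models=6, drop_in=3, base=30.0):
    rng = np.random.default_rng(0)
    tables = {}
    for m in range(n_models):
        rows = []
        for rbp in rbps:
            drop = 2.0 if rbp == drop_rbp and m < drop_in else 1.0
            for group, mean in (("early", base), ("late", base / drop)):
                for rep in range(3):
                    rows.append(
                        {"rbp": rbp, "group": group, "replicate": rep,
                         "value": mean * rng.lognormal(0, 0.03)}
                    )
        tables[f"model{m}"] = pd.DataFrame(rows)
    return tables


def _intron_table(n_per_class=30, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    pos = 1000
    for cls, label in (("change", "up_IR"), ("none", "no_IR")):
        for i in range(n_per_class):
            length = 1000
            rows.append(
                {"intron_id": f"{cls}{i}", "chrom": "chr1", "start": pos,
                 "end": pos + length, "length": length, "label": label}
            )
            pos += length + 500
    return pd.DataFrame(rows)


def _sites_for(introns, rbp, rate_by_label, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for row in introns.itertuples():
        n = rng.poisson(rate_by_label[row.label] * row.length / 1000)
        for _ in range(n):
            s = int(rng.integers(row.start, row.end - 30))
            rows.append({"chrom": "chr1", "start": s, "end": s + 30,
                         "rbp": rbp, "source": ""})
    return rows


class TestCandidateScreen:
    def test_planted_regulator_passes_and_nulls_fail(self):
        introns = _intron_table()
        rows = _sites_for(introns, "REG", {"up_IR": 10.0, "no_IR": 2.0}, seed=1)
        rows += _sites_for(introns, "FLAT", {"up_IR": 2.0, "no_IR": 2.0}, seed=2)
        rows += _sites_for(introns, "LOWEXPR",
                           {"up_IR": 10.0, "no_IR": 2.0}, seed=3)
        idx = BindingSiteIndex(sites=pd.DataFrame(rows))
        expr = _expression_tables(["REG", "FLAT", "LOWEXPR"], drop_rbp="REG")
        # LOWEXPR: enriched and changing but expressed at 8 RPKM everywhere
        for tab in expr.values():
            tab.loc[tab["rbp"] == "LOWEXPR", "value"] = 8.0
        expr["model0"].loc[expr["model0"]["rbp"] == "LOWEXPR", "value"] = [
            8.0, 8.1, 7.9, 4.0, 4.1, 3.9,
        ]
        res = rbp_candidate_screen({"ds": (idx, introns)}, expr, ScreenConfig())
        assert bool(res.loc["REG", "candidate"])
        assert not bool(res.loc["FLAT", "crit1_density"])
        assert not bool(res.loc["FLAT", "candidate"])
        assert not bool(res.loc["LOWEXPR", "crit3_expression_floor"])
        assert not bool(res.loc["LOWEXPR", "candidate"])

    def test_criterion1_must_hold_in_every_dataset(self):
        introns = _intron_table()
        enriched = _sites_for(introns, "REG", {"up_IR": 10.0, "no_IR": 2.0},
                              seed=4)
        flat = _sites_for(introns, "REG", {"up_IR": 2.0, "no_IR": 2.0}, seed=5)
        idx1 = BindingSiteIndex(sites=pd.DataFrame(enriched))
        idx2 = BindingSiteIndex(sites=pd.DataFrame(flat))
        expr = _expression_tables(["REG"], drop_rbp="REG")
        res = rbp_candidate_screen(
            {"ds1": (idx1, introns), "ds2": (idx2, introns)}, expr
        )
        assert not bool(res.loc["REG", "crit1_density"])

    def test_missing_expression_tables_error(self):
        introns = _intron_table()
        idx = BindingSiteIndex(
            sites=pd.DataFrame(columns=["chrom", "start", "end", "rbp",
                                        "source"])
        )
        with pytest.raises(ValueError, match="model"):
            rbp_candidate_screen({"ds": (idx, introns)},
                                 {"only_one": pd.DataFrame(
                                     columns=["rbp", "group", "replicate",
                                              "value"])})


class TestTargetScreen:
    def _tables(self):
        rep = pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "label": ["up_IR", "no_IR", "up_IR"],
            },
            index=pd.Index(["iA", "iB", "iC"], name="intron_id"),
        )
        kd = pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "label": ["up_IR", "up_IR", "up_IR"],
                "delta_iri": [0.3, 0.25, 0.2],
            },
            index=pd.Index(["iA", "iB", "iC"], name="intron_id"),
        )
        fc = pd.Series({"gA": -0.8, "gB": -0.5, "gC": -0.6})
        recs = [
            _record("iA", "gA", 1000, 2000, fu=(800, 1000), fd=(2000, 2200)),
            _record("iB", "gB", 3000, 4000, fu=(2800, 3000), fd=(4000, 4200)),
            _record("iC", "gC", 5000, 6000, fu=(4800, 5000), fd=(6000, 6200)),
        ]
        return rep, kd, fc, recs

    def test_all_criteria(self):
        rep, kd, fc, recs = self._tables()
        peaks = BindingSiteIndex(
            sites=pd.DataFrame(
                {
                    # peak inside iA; peak in a flank of iC; none near iB
                    "chrom": ["chr1", "chr1"],
                    "start": [1500, 4850],
                    "end": [1530, 4880],
                    "rbp": ["U", "U"],
                    "source": ["", ""],
                }
            )
        )
        res = target_gene_screen(rep, kd, fc, peaks, recs, rbp="U")
        assert bool(res.loc["iA", "candidate"])  # everything met, peak in intron
        assert not bool(res.loc["iB", "candidate"])  # not changed in replicative
        assert not bool(res.loc["iB", "crit1_both_changed"])
        assert bool(res.loc["iC", "crit3_peak"])  # peak in flanking exon
        assert bool(res.loc["iC", "candidate"])
        # sorted by |delta IRI| descending
        assert list(res.index) == ["iA", "iB", "iC"]
        # output restricted to change-class introns of the KD table
        assert set(res.index) <= set(kd.index[kd["label"].isin(
            ["up_IR", "down_IR"])])

    def test_positive_fc_fails_anticorrelation(self):
        rep, kd, fc, recs = self._tables()
        fc["gA"] = +0.8
        peaks = BindingSiteIndex(
            sites=pd.DataFrame({"chrom": ["chr1"], "start": [1500],
                                "end": [1530], "rbp": ["U"], "source": [""]})
        )
        res = target_gene_screen(rep, kd, fc, peaks, recs, rbp="U")
        assert not bool(res.loc["iA", "crit2_anticorrelated"])

    def test_universe_mismatch_errors(self):
        rep, kd, fc, recs = self._tables()
        with pytest.raises(ValueError, match="different introns"):
            target_gene_screen(rep.iloc[:2], kd, fc,
                               BindingSiteIndex(sites=pd.DataFrame(
                                   columns=["chrom", "start", "end", "rbp",
                                            "source"])),
                               recs)
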