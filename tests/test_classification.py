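import pandas as pd
import pytest

from ipactools.classification import (
    ClassificationConfig,
    IPACClass,
    a_ipac_antisense_breakdown,
    class_summary,
    classify_ipacs,
)
from ipactools.errors import PairingError
from ipactools.genome_model import ExtendedAnnotation
from ipactools.neighborhood import NeighborContext
from ipactools.pac_annotation import AnnotatedPAC, RegionCategory
from ipactools.pat_processing import PAC, CleavageSite

from .conftest import make_gene

NEUTRAL = {"c": "ACGT" * 5000}  # 25 % A, 50 % A+G everywhere: filter keeps


def ipac(pos=1000, strand="+", antisense_gene=None):
    pac = PAC("c", strand, pos, pos, [CleavageSite("c", pos, strand, 3)])
    return AnnotatedPAC(pac, RegionCategory.INTERGENIC, antisense_gene=antisense_gene)


def classify_one(ctx, ip=None, cfg=None, genome=NEUTRAL):
    recs = classify_ipacs([ip or ipac()], [ctx], cfg or ClassificationConfig(), genome)
    return recs[0].label


class TestRuleCascade:
    def test_se_within_cutoff(self):
        assert classify_one(NeighborContext(d5s=300)) is IPACClass.SE

    def test_se_boundary_is_strict(self):
        assert classify_one(NeighborContext(d5s=700)) is not IPACClass.SE
        assert classify_one(NeighborContext(d5s=699)) is IPACClass.SE

    def test_antisense_overlap_clean_downstream_is_a(self):
        label = classify_one(
            NeighborContext(d5s=1500), ip=ipac(antisense_gene="X")
        )
        assert label is IPACClass.A

    def test_antisense_overlap_a_rich_is_filtered(self):
        genome = {"c": "C" * 1000 + "A" * 20 + "C" * 1000}
        label = classify_one(
            NeighborContext(d5s=1500), ip=ipac(antisense_gene="X"), genome=genome
        )
        assert label is IPACClass.FILTERED_IP

    def test_rule_cascade_to_so(self):
        ctx = NeighborContext(d5s=2500, d3a=3000, d5a=5000, d3s=4000)
        assert classify_one(ctx) is IPACClass.SO

    def test_antisense_proximal(self):
        ctx = NeighborContext(d5s=2500, d5a=150, d3a=5000, d3s=4000)
        assert classify_one(ctx) is IPACClass.ANTISENSE_PROXIMAL

    def test_sense_promoter(self):
        ctx = NeighborContext(d5s=2500, d5a=500, d3a=5000, d3s=400)
        assert classify_one(ctx) is IPACClass.SENSE_PROMOTER

    def test_se_wins_over_antisense_overlap(self):
        label = classify_one(NeighborContext(d5s=100), ip=ipac(antisense_gene="X"))
        assert label is IPACClass.SE

    def test_absent_d5s_skips_se(self):
        ctx = NeighborContext(d5s=None, d3s=4000, d5a=5000, d3a=5000)
        assert classify_one(ctx) is IPACClass.SO

    def test_so_antisense_cutoff_variant(self):
        cfg = ClassificationConfig(so_antisense_cutoff_nt=700)
        ctx = NeighborContext(d5s=2500, d3a=500, d5a=5000, d3s=4000)
        assert classify_one(ctx, cfg=cfg) is IPACClass.ANTISENSE_PROXIMAL
        assert classify_one(ctx) is IPACClass.SO  # default 200-nt rule only

    def test_misaligned_contexts_rejected(self):
        with pytest.raises(PairingError):
            classify_ipacs([ipac()], [], ClassificationConfig(), NEUTRAL)


class TestPartitionAndMonotonicity:
    def _random_contexts(self, rng, n=300):
        out = []
        for _ in range(n):
            out.append(
                (
                    ipac(antisense_gene="X" if rng.random() < 0.2 else None),
                    NeighborContext(
                        d5s=int(rng.integers(0, 3000)),
                        d3s=int(rng.integers(0, 3000)),
                        d5a=int(rng.integers(0, 3000)),
                        d3a=int(rng.integers(0, 3000)),
                    ),
                )
            )
        return out

    def test_labels_partition(self, rng):
        pairs = self._random_contexts(rng)
        recs = classify_ipacs(
            [p[0] for p in pairs], [p[1] for p in pairs], ClassificationConfig(), NEUTRAL
        )
        assert len(recs) == len(pairs)
        s = class_summary(recs).set_index("class")
        total = sum(s.loc[c.value, "n"] for c in IPACClass)
        assert total == len(pairs) == s.loc["TOTAL", "n"]

    def test_raising_se_cutoff_monotone(self, rng):
        pairs = self._random_contexts(rng)
        ip, ctx = [p[0] for p in pairs], [p[1] for p in pairs]
        n_se = [
            sum(
                r.label is IPACClass.SE
                for r in classify_ipacs(ip, ctx, ClassificationConfig(se_cutoff_nt=c), NEUTRAL)
            )
            for c in (300, 700, 1500)
        ]
        assert n_se == sorted(n_se)

    def test_raising_proximal_cutoff_monotone(self, rng):
        pairs = self._random_contexts(rng)
        ip, ctx = [p[0] for p in pairs], [p[1] for p in pairs]
        n_prox = [
            sum(
                r.label is IPACClass.ANTISENSE_PROXIMAL
                for r in classify_ipacs(
                    ip, ctx, ClassificationConfig(antisense_proximal_cutoff_nt=c), NEUTRAL
                )
            )
            for c in (100, 200, 600)
        ]
        assert n_prox == sorted(n_prox)


class TestClassSummary:
    def test_prefilter_candidates_arithmetic(self):
        # 5 A candidates, 2 filtered -> 3 A post-filter, 5 pre-filter
        ips, ctxs, genomes = [], [], []
        genome = {"c": "C" * 500 + "A" * 20 + "ACGT" * 500}
        for i, pos in enumerate((500, 2000, 2200, 2400, 2600)):
            ips.append(ipac(pos=pos, antisense_gene="X"))
            ctxs.append(NeighborContext(d5s=1500))
        # position 500 has the A-rich downstream; 505 still sees 17/20 A
        ips.append(ipac(pos=505, antisense_gene="X"))
        ctxs.append(NeighborContext(d5s=1500))
        recs = classify_ipacs(ips, ctxs, ClassificationConfig(), genome)
        s = class_summary(recs).set_index("class")
        assert s.loc["A_candidates_prefilter", "n"] == 6
        assert s.loc["FILTERED_IP", "n"] == 2
        assert s.loc["A", "n"] == 4

    def test_all_se(self):
        recs = classify_ipacs(
            [ipac(), ipac()], [NeighborContext(d5s=1), NeighborContext(d5s=2)],
            ClassificationConfig(), NEUTRAL,
        )
        s = class_summary(recs).set_index("class")
        assert s.loc["SE", "n"] == 2
        assert s.loc["SO", "n"] == 0

    def test_empty(self):
        s = class_summary([]).set_index("class")
        assert (s.loc[[c.value for c in IPACClass], "n"] == 0).all()


class TestAntisenseBreakdown:
    @pytest.fixture
    def ann_with_gene(self):
        g = make_gene("host", "c", "-", 1000, 3000,
                      exons=[(1000, 1800), (2000, 3000)],
                      cds=[(1150, 1800), (2000, 2900)])
        return ExtendedAnnotation([g], {"c": 20000}, extension_nt=50)

    def _record(self, pos, ann, genome=NEUTRAL):
        ip = ipac(pos=pos, antisense_gene="host")
        return classify_ipacs([ip], [NeighborContext(d5s=1500)],
                              ClassificationConfig(), genome)[0]

    def test_cds_bucket(self, ann_with_gene):
        recs = [self._record(2500, ann_with_gene)]
        df = a_ipac_antisense_breakdown(recs, ann_with_gene)
        assert df[(df.kind == "region") & (df.key == "CDS")]["n"].item() == 1
        assert df[(df.kind == "biotype") & (df.key == "protein_coding")]["n"].item() == 1

    def test_intron_bucket(self, ann_with_gene):
        df = a_ipac_antisense_breakdown([self._record(1900, ann_with_gene)], ann_with_gene)
        assert df[(df.kind == "region") & (df.key == "intron")]["n"].item() == 1

    def test_empty_a_set(self, ann_with_gene):
        assert a_ipac_antisense_breakdown([], ann_with_gene).empty


class TestPlantedRecovery:
    def test_recovery_at_least_90pct(self, sim_paths, pipeline_run):
        cfg, manifest = pipeline_run
        truth = pd.read_csv(sim_paths["truth"], sep="\t")
        rec = pd.read_csv(f"{cfg.outdir}/ipac_classes.tsv", sep="\t")
        expected_label = {
            "SE": "SE", "A": "A", "SO": "SO",
            "sense_promoter": "SENSE_PROMOTER",
            "antisense_proximal": "ANTISENSE_PROXIMAL",
        }
        ok = total = 0
        for t in truth.itertuples():
            if t.planted_class == "UTR3":
                continue
            want = "FILTERED_IP" if t.is_internal_priming_artifact else expected_label[t.planted_class]
            hit = rec[
                (rec.chrom == t.chrom)
                & (rec.strand == t.strand)
                & ((rec.dominant_site - t.pos).abs() <= 2)
            ]
            total += 1
            if len(hit) == 1 and hit.iloc[0]["class"] == want:
                ok += 1
        assert total >= 100
        assert ok / total >= 0.90

    def test_artifact_removal_at_least_95pct(self, sim_paths, pipeline_run):
        cfg, _ = pipeline_run
        truth = pd.read_csv(sim_paths["truth"], sep="\t")
        rec = pd.read_csv(f"{cfg.outdir}/ipac_classes.tsv", sep="\t")
        arts = truth[truth.is_internal_priming_artifact]
        assert len(arts) >= 10
        removed = 0
        for t in arts.itertuples():
            hit = rec[
                (rec.chrom == t.chrom)
                & (rec.strand == t.strand)
                & ((rec.dominant_site - t.pos).abs() <= 2)
            ]
            if len(hit) == 1 and hit.iloc[0]["class"] == "FILTERED_IP":
                removed += 1
        assert removed / len(arts) >= 0.95
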