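import numpy as np
import pandas as pd
import pytest

from salnc.annotation import GenomicInterval, TranscriptModel, TranscriptSet


def make_transcript(
    tid,
    exons,
    biotype="lncRNA",
    chrom="chr1",
    strand="+",
    gene_id=None,
    coding_flag=False,
):
    """Shorthand transcript builder: exons as (start, end) pairs."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or f"g_{tid}",
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(s, e) for s, e in exons),
        biotype=biotype,
        coding_flag=coding_flag,
    )


@pytest.fixture
def two_exon_transcript():
    return make_transcript("t1", [(101, 200), (301, 450)])


@pytest.fixture
def mixed_set():
    """Two lncRNA candidates and one mRNA sharing an exon with one of them."""
    return TranscriptSet(
        [
            make_transcript("lnc_clean", [(5000, 5300), (5500, 5800)]),
            make_transcript("lnc_hit", [(101, 200), (301, 450)]),
            make_transcript("m1", [(150, 250), (400, 600)], biotype="mRNA"),
        ]
    )


# TMM oracle fixtures: literal matrices with factors computed once by the
# reference implementation (Bioconductor edgeR 4.0.16 calcNormFactors,
# method="TMM") and frozen here.
TMM_6X3 = [
    [87, 350, 169],
    [63, 357, 205],
    [5000, 9000, 4000],
    [24, 270, 36],
    [337, 81, 31],
    [176, 399, 228],
]
TMM_6X3_FACTORS = [1.012167477743, 0.995139530526, 0.992804284982]

TMM_50X4 = [
    [837, 330, 23, 483], [611, 865, 869, 845], [819, 158, 296, 593],
    [620, 202, 969, 602], [134, 534, 527, 214], [198, 2, 812, 866],
    [588, 871, 752, 780], [467, 5, 5, 427], [200, 364, 153, 67],
    [885, 515, 674, 157], [15, 831, 209, 171], [452, 432, 250, 414],
    [234, 553, 429, 496], [421, 207, 722, 620], [691, 362, 182, 79],
    [519, 720, 295, 45], [686, 437, 105, 466], [841, 433, 427, 714],
    [852, 108, 20, 687], [489, 746, 132, 429], [679, 593, 157, 534],
    [392, 202, 650, 775], [492, 384, 224, 262], [290, 465, 13, 837],
    [764, 878, 116, 765], [775, 743, 662, 314], [100, 391, 749, 465],
    [572, 684, 928, 264], [916, 383, 306, 399], [934, 922, 291, 396],
    [570, 130, 919, 556], [154, 419, 106, 409], [250, 191, 99, 422],
    [680, 537, 470, 750], [255, 424, 514, 278], [356, 465, 105, 920],
    [410, 610, 709, 638], [878, 952, 776, 109], [791, 753, 670, 568],
    [636, 896, 901, 996], [760, 580, 962, 658], [629, 119, 51, 701],
    [290, 903, 523, 939], [406, 671, 16, 877], [308, 99, 308, 309],
    [108, 523, 387, 378], [791, 7, 639, 648], [298, 33, 33, 684],
    [595, 591, 906, 129], [14, 624, 647, 720],
]
TMM_50X4_FACTORS = [0.988763941703, 1.012565433466, 0.991169928622, 1.007711384344]


@pytest.fixture
def tmm_oracle_6x3():
    return pd.DataFrame(TMM_6X3, columns=["a", "b", "c"]), np.array(TMM_6X3_FACTORS)


@pytest.fixture
def tmm_oracle_50x4():
    return (
        pd.DataFrame(TMM_50X4, columns=["a", "b", "c", "d"]),
        np.array(TMM_50X4_FACTORS),
    )
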