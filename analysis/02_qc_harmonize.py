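"""Harmonize the disease pair and apply the study QC filters.

Mirrors the study processing rules: the DCM-like scan keeps variants with >=70%
of the maximum effective sample size, the HCM-like scan >=96% of the total
sample size, and both drop the extended MYBPC3 region
(chr11:29,978,453-80,288,956).  On this synthetic panel sample sizes are
uniform and chromosome 11 holds 1/22 of the blocks, so only the region filter
bites; the counts are reported per filter either way.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import outdir, study_data

from cardiocc.sumstats import MYBPC3_REGION, QCConfig, apply_qc, harmonize_pair, write_sumstats


def main() -> None:
    _, a, b, _, _ = study_data()
    qc_a = QCConfig(min_fraction_n=0.70, n_mode="effective",
                    excluded_regions=[MYBPC3_REGION])
    qc_b = QCConfig(min_fraction_n=0.96, n_mode="total",
                    excluded_regions=[MYBPC3_REGION])
    a_f = apply_qc(a, qc_a)
    b_f = apply_qc(b, qc_b)
    ha, hb = harmonize_pair(a_f, b_f)

    out = outdir("qc")
    write_sumstats(ha, out / f"{ha.trait_label}_qc.tsv")
    write_sumstats(hb, out / f"{hb.trait_label}_qc.tsv")

    print(f"{a.trait_label}: {len(a)} -> {len(a_f)} after QC {a_f.meta['qc_removed']}")
    print(f"{b.trait_label}: {len(b)} -> {len(b_f)} after QC {b_f.meta['qc_removed']}")
    print(f"harmonized intersection: {len(ha)} variants "
          f"({ha.meta['n_irreconcilable']} irreconcilable)")


if __name__ == "__main__":
    main()
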