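"""Apply the final-round variant filter (biallelic SNPs, qual >= 30,
pooled alt frequency >= 1%, coverage within bounds, per-population
frequency consistency within 0.2) and report per-rule rejections."""

import json

from _config import CONFIG, MAX_COV, SIM_DIR

from convergescan import FilterProfile, filter_variants
from convergescan.io import read_scan_table, write_scan_table

profile = FilterProfile.final(MAX_COV)
report_all = {}
for sp in CONFIG.species_ids:
    table = read_scan_table(SIM_DIR / f"{sp}.scanstats.tsv")
    passed, report = filter_variants(table, profile)
    write_scan_table(passed, SIM_DIR / f"{sp}.filtered.tsv")
    report_all[sp] = report.to_dict()
    rej = ", ".join(f"{k}: {v}" for k, v in report.rejected.items()) or "none"
    print(f"{sp}: {report.n_passed}/{report.n_input} SNPs pass; rejected {rej}")

(SIM_DIR / "filter_report.json").write_text(json.dumps(report_all, indent=2))
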