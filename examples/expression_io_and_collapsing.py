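"""Reading TSV expression data and collapsing probes to gene symbols.

Writes a toy probe-level matrix and sample sheet to disk, reads them back
with validation, collapses the probes of each gene by their per-sample
median, and builds the sex-stratified sample groups.
"""

import tempfile
from pathlib import Path

from mcoselect import build_groups, collapse_probes, read_expression

tmp = Path(tempfile.mkdtemp())
(tmp / "matrix.tsv").write_text(
    "feature\ts1\ts2\ts3\ts4\n"
    "probe1\t1.0\t2.0\t6.0\t7.0\n"   # probe1/probe2 both measure gene TUB1
    "probe2\t3.0\t4.0\t8.0\t9.0\n"
    "probe3\t5.0\t5.0\t5.0\t5.0\n"
)
(tmp / "sheet.tsv").write_text(
    "sample\tcondition\tsex\n"
    "s1\tHealthy\tF\n"
    "s2\tHealthy\tM\n"
    "s3\tPD\tF\n"
    "s4\tPD\tM\n"
)

# study-specific labels are folded into case/control only via an explicit map
ds = read_expression(
    tmp / "matrix.tsv", tmp / "sheet.tsv", dataset_id="toy",
    label_map={"Healthy": "control", "PD": "case"},
)
print(f"read {ds.n_features} probes x {ds.n_samples} samples")

collapsed = collapse_probes(ds, {"probe1": "TUB1", "probe2": "TUB1", "probe3": "ACT2"})
print("gene-level matrix (per-sample median over each gene's probes):")
print(collapsed.values)

groups = build_groups(collapsed, stratify_by_sex=True)
print("groups:", {name: list(g.member_sample_ids) for name, g in groups.items()})
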