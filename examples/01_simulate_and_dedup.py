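"""Generate a synthetic FAERS quarter, re-read it, and deduplicate cases.

Spontaneous-report databases republish a case each time its report is
amended, so one case (CASEID) maps to several report versions
(PRIMARYID).  Analyses must keep exactly one version per case: the one
with the latest FDA receipt date, ties broken by the highest PRIMARYID.
"""

import tempfile

from pvsignal import (
    ReportKey,
    SynthConfig,
    deduplicate,
    deduplicate_reports,
    generate_quarter,
    read_quarter,
)

# The classic four-version worked example: only the newest version survives.
keys = [
    ReportKey(4271953, 4070800, 20040113),
    ReportKey(4271960, 4070800, 20040113),
    ReportKey(4283861, 4070800, 20040130),
    ReportKey(4314767, 4070800, 20040308),
]
for d in deduplicate(keys):
    print(f"caseid {d.key.caseid}  fda_dt {d.key.fda_dt}  primaryid {d.key.primaryid}"
          f"  retained={d.retained} ({d.reason})")

# A whole quarter: 5,000 reports, 10% of cases republished as amended versions.
cfg = SynthConfig(n_reports=5000, seed=1, duplicate_rate=0.10)
with tempfile.TemporaryDirectory() as tmp:
    generate_quarter(cfg, tmp)
    reports, assembly = read_quarter(tmp)
    kept, decisions = deduplicate_reports(reports)

print(f"\nparsed {assembly.n_reports} report versions "
      f"({assembly.total_orphans()} orphan child rows)")
print(f"deduplicated to {len(kept)} cases "
      f"({assembly.n_reports - len(kept)} amended versions removed)")
# With duplicate_rate=0.10 the version count exceeds the case count by
# the injected amendments; after deduplication exactly n_reports cases remain.
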