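"""Annotate a fusion with cancer-census roles and its domain architecture.

The census lookup is a case-insensitive exact-symbol match returning the
partner's role (oncogene / TSG / oncogene+TSG / fusion / unknown) with
its tumor and mutation type lists. Domain retention is computed in
protein coordinates: the 5' partner keeps its N-terminal side up to the
breakpoint, the 3' partner keeps its C-terminal side.
"""

from fusiontriage import (
    CensusRecord,
    DomainRecord,
    FusionCandidate,
    classify_cancer_gene,
    fusion_domain_layout,
)

census = {
    r.key: r
    for r in [
        CensusRecord("CUX1", "TSG", ["myeloid"], ["frameshift"]),
        CensusRecord("RET", "oncogene", ["NSCLC", "thyroid"], ["translocation"]),
    ]
}
domains = {
    "cux1": [
        DomainRecord("CUX1", "CUT", 542, 628, "PF02376"),
        DomainRecord("CUX1", "homeobox", 1121, 1180, "PF00046"),
    ],
    "ret": [
        DomainRecord("RET", "cadherin", 29, 152, "PF00028"),
        DomainRecord("RET", "kinase", 724, 1005, "PF07714"),
    ],
}

fusion = FusionCandidate("CUX1", "RET")
roles = classify_cancer_gene(fusion, census)
print(f"{roles.fusion_id}: 5'={roles.partner5.role}, 3'={roles.partner3.role}, "
      f"oncogenic partner: {roles.oncogenic_partner}")

layout = fusion_domain_layout(fusion, domains, breakpoint5_aa=700, breakpoint3_aa=700)
for label, track in (("5'", layout.partner5), ("3'", layout.partner3)):
    for ds in track:
        d = ds.domain
        print(f"  {label} {d.symbol} {d.domain_name} [{d.start_aa}-{d.end_aa}]: {ds.status}")
# With a 5' breakpoint at aa 700 CUX1 keeps CUT but loses its homeobox;
# with a 3' breakpoint at aa 700 RET loses cadherin but keeps the intact
# kinase domain — the classic architecture of an activating kinase fusion.
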