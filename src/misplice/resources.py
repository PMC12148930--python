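"""In-repo reference inputs: published assay template sequences and the
canonical RBP motif pattern strings used throughout the analyses.

The two RNA templates below are the filter-binding assay substrates for the
MBNL1-Ank2 interaction (DNA alphabet; the leading lowercase g of the in
vitro transcription template is kept).  The wild-type template carries one
tripartite MBNL element TGCT(N)3TGCT(N)13-18TGC[T/C] downstream of the Ank2
microexon 5' splice site; the mutant destroys all three TGCT cores.
"""

from .motifs import ANK2_TRIPARTITE, MBNL_GAPPED, MBNL_YGCY, RBFOX_GCAYG  # noqa: F401

ANK2_TEMPLATE = (
    "gGGAACCTTGGTCTTCCTGGGTTCATTCGCATTTCCCTGCTTCCTGCTCATCACAGCTCACTGCTCACTGTGTGTGTTTGTGTGTGTGTG"
)

ANK2_MUT_TEMPLATE = (
    "gGGAACCTTGGTCTTCCTGGGTTCATTCGCATTTCCCGGCTTCCTGATCATCACAGCTCACTGTTCACTGTGTGTGTTTGTGTGTGTGTG"
)

#: Dyad counts behind the threat-communication comparison: 7% of 15 WT and
#: 36% of 14 KO dyads, uniquely 1/15 and 5/14 at the printed group sizes.
THREAT_DYADS = {"k_wt": 1, "n_wt": 15, "k_ko": 5, "n_ko": 14}

#: Dominance comparison: 67% of 15 WT vs 14% of 14 KO dyads -> 10/15 vs 2/14.
DOMINANCE_DYADS = {"k_wt": 10, "n_wt": 15, "k_ko": 2, "n_ko": 14}
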