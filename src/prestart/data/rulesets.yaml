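# Built-in tool variants.
#
# A participant is high risk under a variant when every `core` factor is
# present AND at least one `plus_one` factor is present.
#
# `initial` is the original tool (core: overweight/obese + screen time,
# plus-one: the other thirteen factors).  tool1..tool12 remove plus-one
# factors cumulatively in the published order:
#   AN, FLD, PCOS, SI, MS, FH, PDM, ETH, OP, BF, SGA, WG04
# so tool12's plus-one set is {WC} alone — high waist circumference is
# never listed as removed and is retained in every variant.
#
# tool13..tool21 are the collaboration-requested amendments:
#   tool13: screen time dropped from core; plus-one reconstructed from its
#           published row ("- AN, FLD, PCOS, SI, MS, FH, PDM, ETH, OP, BF,
#           SGA" relative to the full thirteen-factor set), i.e. {WC, WG04}.
#           The source row's formatting is degraded; this reconstruction
#           keeps exactly the factors never struck from the row.
#   tool14: + OP, BF        (parental obesity, breast feeding restored)
#   tool15: - WG04          (rapid-weight-gain question dropped)
#   tool16: + FH2           (family history extended to 2nd degree)
#   tool17: + SI
#   tool18: + ST
#   tool19: + LPA
#   tool20: + LFV           (the final tool)
#   tool21: + AN            (assessed but not adopted)

rulesets:
  - name: initial
    core: [OO, ST]
    plus_one: [WC, AN, FH, ETH, MS, WG04, PDM, SI, FLD, OP, PCOS, SGA, BF]

  - name: tool1
    core: [OO, ST]
    plus_one: [WC, FH, ETH, MS, WG04, PDM, SI, FLD, OP, PCOS, SGA, BF]
  - name: tool2
    core: [OO, ST]
    plus_one: [WC, FH, ETH, MS, WG04, PDM, SI, OP, PCOS, SGA, BF]
  - name: tool3
    core: [OO, ST]
    plus_one: [WC, FH, ETH, MS, WG04, PDM, SI, OP, SGA, BF]
  - name: tool4
    core: [OO, ST]
    plus_one: [WC, FH, ETH, MS, WG04, PDM, OP, SGA, BF]
  - name: tool5
    core: [OO, ST]
    plus_one: [WC, FH, ETH, WG04, PDM, OP, SGA, BF]
  - name: tool6
    core: [OO, ST]
    plus_one: [WC, ETH, WG04, PDM, OP, SGA, BF]
  - name: tool7
    core: [OO, ST]
    plus_one: [WC, ETH, WG04, OP, SGA, BF]
  - name: tool8
    core: [OO, ST]
    plus_one: [WC, WG04, OP, SGA, BF]
  - name: tool9
    core: [OO, ST]
    plus_one: [WC, WG04, SGA, BF]
  - name: tool10
    core: [OO, ST]
    plus_one: [WC, WG04, SGA]
  - name: tool11
    core: [OO, ST]
    plus_one: [WC, WG04]
  - name: tool12
    core: [OO, ST]
    plus_one: [WC]

  - name: tool13
    core: [OO]
    plus_one: [WC, WG04]
  - name: tool14
    core: [OO]
    plus_one: [WC, WG04, OP, BF]
  - name: tool15
    core: [OO]
    plus_one: [WC, OP, BF]
  - name: tool16
    core: [OO]
    plus_one: [WC, OP, BF, FH2]
  - name: tool17
    core: [OO]
    plus_one: [WC, OP, BF, FH2, SI]
  - name: tool18
    core: [OO]
    plus_one: [WC, OP, BF, FH2, SI, ST]
  - name: tool19
    core: [OO]
    plus_one: [WC, OP, BF, FH2, SI, ST, LPA]
  - name: tool20
    core: [OO]
    plus_one: [WC, OP, BF, FH2, SI, ST, LPA, LFV]
  - name: tool21
    core: [OO]
    plus_one: [WC, OP, BF, FH2, SI, ST, LPA, LFV, AN]

aliases:
  final: tool20
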