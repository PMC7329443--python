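# Pathway-completeness grammar for vent-chimney MAG annotation.
# Levels are evaluated in order (complete -> uncomplete -> partial);
# the first matching rule wins, the default level is "none"
# ("absent" for binary traits).  Expressions: a bare string is a gene
# symbol; {all: [...]}, {any: [...]}, {atleast: k, of: [...]}.
notes:
  dsrAB_aprAB: >-
    Slash-joined gene pairs (dsrAB, aprAB, nrfA/H) are treated as groups
    requiring all members; set "any" in the rule to relax.
  sox_partial: >-
    "Partial" Sox is read as any of soxA/soxX/soxY/soxZ; soxC/soxD alone
    do not trigger partial (soxB alone is uncomplete and takes
    precedence when present).
  wl_partial: >-
    "Partial" Wood-Ljungdahl is read as at least 2 of the three groups
    (cdhC|cdhB), (cdhE|cdhD), cooS without the full complete/uncomplete
    conditions.
  fermentation: >-
    The fermentation marker set {ldh, adhE, por} is a package vocabulary
    choice; edit to taste.
pathways:
  sulfide_oxidation:
    binary: false
    levels:
      - level: complete
        rule: {any: [sqr, fccB]}
  sox:
    binary: false
    levels:
      - level: complete
        rule: {all: [soxA, soxB, soxX, soxY, soxZ, soxC, soxD]}
      - level: uncomplete
        rule: soxB
      - level: partial
        rule: {any: [soxA, soxX, soxY, soxZ]}
  dsr:
    binary: false
    levels:
      - level: complete
        rule: {atleast: 3, of: [sat, {all: [dsrA, dsrB]}, {all: [aprA, aprB]}]}
      - level: uncomplete
        rule: {atleast: 2, of: [sat, {all: [dsrA, dsrB]}, {all: [aprA, aprB]}]}
      - level: partial
        rule: {atleast: 1, of: [sat, {all: [dsrA, dsrB]}, {all: [aprA, aprB]}]}
  dnra:
    binary: false
    levels:
      - level: complete
        rule: {any: [nirB, {all: [nrfA, nrfH]}]}
      - level: uncomplete
        rule: {any: [nrfA, nrfH]}
  denitrification:
    binary: false
    levels:
      - level: complete
        rule: {atleast: 3, of: [{any: [nirS, nirK]}, {any: [norB, norC]}, nosZ]}
      - level: uncomplete
        rule: {atleast: 2, of: [{any: [nirS, nirK]}, {any: [norB, norC]}, nosZ]}
      - level: partial
        rule: {atleast: 1, of: [{any: [nirS, nirK]}, {any: [norB, norC]}, nosZ]}
  nitrogen_fixation:
    binary: false
    levels:
      - level: complete
        rule: {all: [nifK, nifD, nifH]}
      - level: uncomplete
        rule: {atleast: 2, of: [nifK, nifD, nifH]}
      - level: partial
        rule: {atleast: 1, of: [nifK, nifD, nifH]}
  wood_ljungdahl:
    binary: false
    levels:
      - level: complete
        rule: {all: [{any: [cdhC, acsB]}, cdhE, cdhD, cooS]}
      - level: uncomplete
        rule: {all: [{any: [cdhC, acsB]}, {any: [cdhE, cdhD]}, cooS]}
      - level: partial
        rule: {atleast: 2, of: [{any: [cdhC, cdhB]}, {any: [cdhE, cdhD]}, cooS]}
  co_oxidation:
    binary: false
    levels:
      - level: complete
        rule: {all: [coxM, coxL, coxS]}
      - level: uncomplete
        rule: {all: [coxL, {any: [coxS, coxM]}]}
      - level: partial
        rule: {atleast: 1, of: [coxM, coxL, coxS]}
  acetate_utilization:
    binary: false
    levels:
      - level: complete
        rule: {any: [ACSS, {all: [pta, ack]}]}
  rtca:
    binary: false
    levels:
      - level: complete
        rule: {all: [aclA, aclB]}
      - level: uncomplete
        rule: {any: [aclA, aclB]}
  cbb:
    binary: false
    levels:
      - level: complete
        rule: {all: [rbcL, rbcS]}
      - level: uncomplete
        rule: {any: [rbcL, rbcS]}
  methanogenesis:
    binary: false
    levels:
      - level: complete
        rule: {all: [mcrA, mcrG, mcrB]}
      - level: uncomplete
        rule: {atleast: 2, of: [mcrA, mcrG, mcrB]}
      - level: partial
        rule: {atleast: 1, of: [mcrA, mcrG, mcrB]}
  cytochrome_c_oxidase:
    binary: false
    levels:
      - level: complete
        rule:
          any:
            - {atleast: 2, of: [coxA, coxB, cydA, cydB, qoxA, qoxB]}
            - {atleast: 3, of: [ccoN, ccoO, ccoP, cyoA, cyoB, cyoC]}
      - level: uncomplete
        rule:
          any:
            - {atleast: 1, of: [coxA, coxB, cydA, cydB, qoxA, qoxB]}
            - {atleast: 2, of: [ccoN, ccoO, ccoP, cyoA, cyoB, cyoC]}
      - level: partial
        rule: {atleast: 1, of: [ccoN, ccoO, ccoP, cyoA, cyoB, cyoC]}
  iron_oxidation_cyc2:
    binary: true
    levels:
      - level: present
        rule: cyc2
  fermentation:
    binary: true
    levels:
      - level: present
        rule: {any: [ldh, adhE, por]}
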