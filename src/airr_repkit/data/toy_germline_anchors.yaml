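# Anchor/region sidecar for the bundled toy germline set.
# Coordinates are 1-based closed positions within each germline sequence.
genes:
  - name: TOYV1-1*01
    segment: V
    junction_start: 61
    regions:
      fwr1: [1, 24]
      cdr1: [25, 33]
      fwr2: [34, 45]
      cdr2: [46, 54]
      fwr3: [55, 60]
  - name: TOYV2-1*01
    segment: V
    junction_start: 61
    regions:
      fwr1: [1, 24]
      cdr1: [25, 33]
      fwr2: [34, 45]
      cdr2: [46, 54]
      fwr3: [55, 60]
  - name: TOYV3-1*01
    segment: V
    junction_start: 61
    regions:
      fwr1: [1, 24]
      cdr1: [25, 33]
      fwr2: [34, 45]
      cdr2: [46, 54]
      fwr3: [55, 60]
  - name: TOYV4-1*01
    segment: V
    junction_start: 61
    regions:
      fwr1: [1, 24]
      cdr1: [25, 33]
      fwr2: [34, 45]
      cdr2: [46, 54]
      fwr3: [55, 60]
  - name: TOYD1*01
    segment: D
  - name: TOYD2*01
    segment: D
  - name: TOYD3*01
    segment: D
  - name: TOYJ1*01
    segment: J
    junction_end: 21
  - name: TOYJ2*01
    segment: J
    junction_end: 18
  - name: TOYJ3*01
    segment: J
    junction_end: 24
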