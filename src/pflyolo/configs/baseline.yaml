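nc: 60
strides:
- 8
- 16
- 32
layers:
- index: 0
  kind: conv
  args:
    cin: 3
    cout: 16
    k: 3
    s: 2
  from:
  - -1
- index: 1
  kind: conv
  args:
    cin: 16
    cout: 32
    k: 3
    s: 2
  from:
  - -1
- index: 2
  kind: c2f
  args:
    cin: 32
    cout: 32
    n: 1
    shortcut: true
  from:
  - -1
- index: 3
  kind: conv
  args:
    cin: 32
    cout: 64
    k: 3
    s: 2
  from:
  - -1
- index: 4
  kind: c2f
  args:
    cin: 64
    cout: 64
    n: 2
    shortcut: true
  from:
  - -1
- index: 5
  kind: conv
  args:
    cin: 64
    cout: 128
    k: 3
    s: 2
  from:
  - -1
- index: 6
  kind: c2f
  args:
    cin: 128
    cout: 128
    n: 2
    shortcut: true
  from:
  - -1
- index: 7
  kind: conv
  args:
    cin: 128
    cout: 256
    k: 3
    s: 2
  from:
  - -1
- index: 8
  kind: c2f
  args:
    cin: 256
    cout: 256
    n: 1
    shortcut: true
  from:
  - -1
- index: 9
  kind: sppf
  args:
    cin: 256
    cout: 256
  from:
  - -1
- index: 10
  kind: upsample
  args:
    scale: 2
  from:
  - -1
- index: 11
  kind: concat
  args: {}
  from:
  - -1
  - 6
- index: 12
  kind: c2f
  args:
    cin: 384
    cout: 128
    n: 1
    shortcut: false
  from:
  - -1
- index: 13
  kind: upsample
  args:
    scale: 2
  from:
  - -1
- index: 14
  kind: concat
  args: {}
  from:
  - -1
  - 4
- index: 15
  kind: c2f
  args:
    cin: 192
    cout: 64
    n: 1
    shortcut: false
  from:
  - -1
- index: 16
  kind: conv
  args:
    cin: 64
    cout: 64
    k: 3
    s: 2
  from:
  - -1
- index: 17
  kind: concat
  args: {}
  from:
  - -1
  - 12
- index: 18
  kind: c2f
  args:
    cin: 192
    cout: 128
    n: 1
    shortcut: false
  from:
  - -1
- index: 19
  kind: conv
  args:
    cin: 128
    cout: 128
    k: 3
    s: 2
  from:
  - -1
- index: 20
  kind: concat
  args: {}
  from:
  - -1
  - 9
- index: 21
  kind: c2f
  args:
    cin: 384
    cout: 256
    n: 1
    shortcut: false
  from:
  - -1
- index: 22
  kind: detect
  args:
    nc: 60
    chs:
    - 64
    - 128
    - 256
  from:
  - 15
  - 18
  - 21
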