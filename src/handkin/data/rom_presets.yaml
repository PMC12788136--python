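# Measured per-joint ROM bounds (degrees, interior-angle convention) for
# single-finger flexion-extension cycles, ground-truth motion-capture column.
# Thumb TM/MCP/IP occupy the mcp/pip/dip slots.
fingers:
  thumb:
    mcp: [100.6, 108.7]
    pip: [130.0, 174.5]
    dip: [143.8, 179.4]
  index:
    mcp: [155.9, 176.4]
    pip: [120.4, 152.9]
    dip: [154.8, 172.4]
  middle:
    mcp: [148.0, 179.3]
    pip: [123.7, 155.7]
    dip: [164.4, 172.1]
  ring:
    mcp: [126.3, 157.5]
    pip: [143.2, 150.9]
    dip: [158.8, 174.1]
  pinky:
    mcp: [150.0, 163.4]
    pip: [129.8, 151.5]
    dip: [159.2, 172.7]
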