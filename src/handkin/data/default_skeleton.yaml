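# Default adult-hand segment lengths in millimetres.
# Order-of-magnitude values for an average adult hand; these are
# configuration for the forward-kinematics layout, not anatomical claims,
# and none of the angle-based metrics depend on them.
# Segments run wrist->MCP (metacarpal), MCP->PIP (proximal phalanx),
# PIP->DIP (middle phalanx), DIP->TIP (distal phalanx).  For the thumb the
# same slots carry the TM-MCP-IP chain.
fingers:
  thumb:
    wrist_mcp: 46.0
    mcp_pip: 36.0
    pip_dip: 30.0
    dip_tip: 25.0
  index:
    wrist_mcp: 85.0
    mcp_pip: 42.0
    pip_dip: 25.0
    dip_tip: 22.0
  middle:
    wrist_mcp: 83.0
    mcp_pip: 46.0
    pip_dip: 28.0
    dip_tip: 24.0
  ring:
    wrist_mcp: 78.0
    mcp_pip: 42.0
    pip_dip: 27.0
    dip_tip: 23.0
  pinky:
    wrist_mcp: 74.0
    mcp_pip: 33.0
    pip_dip: 20.0
    dip_tip: 20.0
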