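{
  "description": "Coarse rectangular Ramachandran region masks, degrees. A residue is favored if (phi,psi) falls in any 'favored' box of its class, else allowed if in any 'allowed' box, else disallowed. Boxes are [phi_min, phi_max, psi_min, psi_max].",
  "classes": {
    "general": {
      "favored": [
        [-160, -30, -80, -5],
        [-180, -40, 90, 180],
        [-180, -40, -180, -170]
      ],
      "allowed": [
        [-180, -20, -120, 45],
        [-180, -20, 45, 180],
        [-180, -20, -180, -140],
        [30, 90, -10, 80]
      ]
    },
    "glycine": {
      "favored": [
        [-160, -30, -80, -5],
        [-180, -40, 90, 180],
        [30, 100, -60, 60]
      ],
      "allowed": [
        [-180, 180, -180, 180]
      ]
    },
    "proline": {
      "favored": [
        [-100, -40, -60, -5],
        [-100, -40, 110, 180]
      ],
      "allowed": [
        [-110, -30, -180, 180]
      ]
    },
    "preproline": {
      "favored": [
        [-160, -30, -80, -5],
        [-180, -40, 90, 180]
      ],
      "allowed": [
        [-180, -20, -120, 45],
        [-180, -20, 45, 180],
        [-180, -20, -180, -140],
        [30, 90, -10, 80]
      ]
    }
  }
}
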