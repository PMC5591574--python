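{
  "description": "Canonical eye-writing digit patterns as waypoint polylines on a 3x3 lattice (column, row), origin bottom-left, +row = up. Each pattern starts at its first waypoint; strokes are straight corner-to-corner saccades. Shapes are simplified to minimize eye movement while keeping the digit recognizable; the '1' keeps its main descender on the centre column.",
  "grid": [3, 3],
  "templates": [
    {"label": 0, "waypoints": [[0, 2], [2, 2], [2, 0], [0, 0], [0, 2]]},
    {"label": 1, "waypoints": [[0, 1], [1, 2], [1, 0]]},
    {"label": 2, "waypoints": [[0, 2], [2, 2], [2, 1], [0, 1], [0, 0], [2, 0]]},
    {"label": 3, "waypoints": [[0, 2], [2, 2], [2, 1], [0, 1], [2, 1], [2, 0], [0, 0]]},
    {"label": 4, "waypoints": [[0, 2], [0, 1], [2, 1], [2, 2], [2, 0]]},
    {"label": 5, "waypoints": [[2, 2], [0, 2], [0, 1], [2, 1], [2, 0], [0, 0]]},
    {"label": 6, "waypoints": [[2, 2], [0, 2], [0, 0], [2, 0], [2, 1], [0, 1]]},
    {"label": 7, "waypoints": [[0, 2], [2, 2], [0, 0]]},
    {"label": 8, "waypoints": [[0, 2], [2, 2], [2, 1], [0, 1], [0, 0], [2, 0], [2, 1], [0, 1], [0, 2]]},
    {"label": 9, "waypoints": [[2, 2], [0, 2], [0, 1], [2, 1], [2, 0]]}
  ]
}
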