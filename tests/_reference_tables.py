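"""Published reference values used as frozen expectations.

Echo-intensity rows (ROI 1 mean, ROI 2 mean, reference mean, and the two
relative gray values on the percent scale) and directional-texture rows
(per-direction GLCM feature values with their E-W, N-S, Cross and Circle
aggregates) for three scan planes of one subject.  Only the aggregation
arithmetic is checked against these numbers; the absolute feature values
depend on source images that are not available.
"""

# plane -> (roi1_mean, roi2_mean, reference_mean, relative1, relative2)
INTENSITY = {
    "plane1": (144.2773, 153.8880, 252.7574, 57.0813, 60.8837),
    "plane2": (146.3016, 159.7064, 252.9822, 57.8308, 63.1295),
    "plane3": (160.5301, 143.6090, 253.5148, 63.3218, 56.6472),
}

# plane -> row label -> (E, N-E, N, N-W, E-W, N-S, Cross, Circle).
# Opposite directions are equal in the published tables (W = E etc.), so
# the four unique directional cells determine all eight.
HOMOGENEITY = {
    "plane1": {
        "ENE1": (0.1445, 0.0936, 0.1152, 0.1329, 0.1445, 0.1152, 0.1299, 0.1216),
        "IDM1": (0.8645, 0.7328, 0.8027, 0.8438, 0.8645, 0.8027, 0.8336, 0.8110),
        "CON1": (0.2815, 0.7587, 0.4661, 0.3251, 0.2815, 0.4661, 0.3738, 0.4579),
        "ENT1": (3.2778, 3.8747, 3.5914, 3.3678, 3.2778, 3.5914, 3.4346, 3.5279),
        "ENE2": (0.1295, 0.1142, 0.1039, 0.0829, 0.1295, 0.1039, 0.1167, 0.1076),
        "IDM2": (0.8504, 0.8135, 0.7860, 0.7105, 0.8504, 0.7860, 0.8182, 0.7901),
        "CON2": (0.3128, 0.4116, 0.5246, 0.8519, 0.3128, 0.5246, 0.4187, 0.5252),
        "ENT2": (3.3915, 3.5550, 3.7006, 3.9894, 3.3915, 3.7006, 3.5460, 3.6591),
    },
    "plane2": {
        "ENE1": (0.1423, 0.0884, 0.1107, 0.1340, 0.1423, 0.1107, 0.1265, 0.1189),
        "IDM1": (0.8668, 0.7232, 0.7992, 0.8524, 0.8668, 0.7992, 0.8330, 0.8104),
        "CON1": (0.2772, 0.8226, 0.4821, 0.3055, 0.2772, 0.4821, 0.3796, 0.4719),
        "ENT1": (3.3212, 3.9847, 3.6685, 3.3817, 3.3212, 3.6685, 3.4949, 3.5890),
        "ENE2": (0.1412, 0.1218, 0.1108, 0.0923, 0.1412, 0.1108, 0.1260, 0.1165),
        "IDM2": (0.8611, 0.8202, 0.7933, 0.7327, 0.8611, 0.7933, 0.8272, 0.8018),
        "CON2": (0.2826, 0.4066, 0.4931, 0.7288, 0.2826, 0.4931, 0.3879, 0.4778),
        "ENT2": (3.2760, 3.4962, 3.6250, 3.8594, 3.2760, 3.6250, 3.4505, 3.5642),
    },
    "plane3": {
        "ENE1": (0.1164, 0.0672, 0.0810, 0.0901, 0.1164, 0.0810, 0.0987, 0.0887),
        "IDM1": (0.8475, 0.6754, 0.7416, 0.7761, 0.8475, 0.7416, 0.7946, 0.7602),
        "CON1": (0.3192, 1.1057, 0.7312, 0.5468, 0.3192, 0.7312, 0.5252, 0.6757),
        "ENT1": (3.5205, 4.2736, 4.0292, 3.8551, 3.5205, 4.0292, 3.7749, 3.9196),
        "ENE2": (0.1125, 0.0825, 0.0750, 0.0627, 0.1125, 0.0750, 0.0937, 0.0832),
        "IDM2": (0.8525, 0.7612, 0.7307, 0.6685, 0.8525, 0.7307, 0.7916, 0.7532),
        "CON2": (0.3083, 0.6506, 0.8302, 1.1954, 0.3083, 0.8302, 0.5692, 0.7461),
        "ENT2": (3.5875, 4.0420, 4.1858, 4.4070, 3.5875, 4.1858, 3.8866, 4.0556),
    },
}


def directional_cells(row):
    """Expand the four unique directional values to all eight compass
    directions (opposite directions equal)."""
    e, ne, n, nw = row[:4]
    return {"E": e, "N-E": ne, "N": n, "N-W": nw,
            "W": e, "S-W": ne, "S": n, "S-E": nw}
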