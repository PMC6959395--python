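"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from the definitions, in the most
literal style possible, and must stay independent of the package's own code
paths (only the distance primitive's *formula* is shared knowledge: the
haversine on a 6371.0 km sphere).
"""

import math

R_KM = 6371.0


def hav_km(a, b):
    """Scalar haversine, written independently of the package."""
    lat1, lon1 = math.radians(a[0]), math.radians(a[1])
    lat2, lon2 = math.radians(b[0]), math.radians(b[1])
    h = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * R_KM * math.asin(math.sqrt(h))


def replay_clustering(points, radius_m=200.0):
    """Step-by-step replay of the incremental place-clustering rule.

    points: list of (lat, lon) in time order. Returns (assignments, centroids)
    with 1-based cluster ids. Also asserts the insertion invariant: at the
    moment of assignment the point lies within radius of its cluster's
    then-current centroid.
    """
    centroids = []  # [lat, lon]
    members = []  # list of point lists
    assignments = []
    for lat, lon in points:
        dists = [hav_km((lat, lon), (c[0], c[1])) * 1000.0 for c in centroids]
        candidates = [(d, j) for j, d in enumerate(dists) if d <= radius_m]
        if not candidates:
            centroids.append([lat, lon])
            members.append([(lat, lon)])
            assignments.append(len(centroids))
        else:
            d, j = min(candidates)
            assert d <= radius_m  # insertion invariant
            members[j].append((lat, lon))
            centroids[j][0] = sum(p[0] for p in members[j]) / len(members[j])
            centroids[j][1] = sum(p[1] for p in members[j]) / len(members[j])
            assignments.append(j + 1)
    return assignments, centroids


def brute_total_distance(points):
    """Sum of consecutive-pair distances over a point list."""
    return sum(hav_km(points[i], points[i + 1]) for i in range(len(points) - 1))


def brute_sd(values):
    """Sample standard deviation with the n-1 denominator."""
    n = len(values)
    if n < 2:
        return float("nan")
    m = sum(values) / n
    return math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))


def brute_gyration(coords, dwell, weighted_centroid=True):
    """Literal evaluation of the dwell-weighted radius of gyration."""
    T = sum(dwell)
    if T <= 0:
        return float("nan")
    if weighted_centroid:
        c = (
            sum(w * p[0] for p, w in zip(coords, dwell)) / T,
            sum(w * p[1] for p, w in zip(coords, dwell)) / T,
        )
    else:
        c = (
            sum(p[0] for p in coords) / len(coords),
            sum(p[1] for p in coords) / len(coords),
        )
    return math.sqrt(sum(w * hav_km(p, c) ** 2 for p, w in zip(coords, dwell)) / T)


def brute_diversity(place_ids):
    """Normalised Shannon entropy of the visit multiset."""
    ids = list(place_ids)
    if not ids:
        return 0.0
    counts = {}
    for p in ids:
        counts[p] = counts.get(p, 0) + 1
    k = len(counts)
    if k <= 1:
        return 0.0
    total = len(ids)
    ent = -sum((c / total) * math.log(c / total) for c in counts.values())
    return ent / math.log(k)
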