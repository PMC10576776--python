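import numpy as np

from somiteclock.kymo import FrontProfile


def profile_from_fn(fn, n_frames: int, factor: int = 10) -> FrontProfile:
    """FrontProfile whose resampled series evaluates ``fn`` on the uniform
    frame grid [0, n_frames - 1], mirroring smooth_resample's re-gridding."""
    frames = np.arange(n_frames, dtype=float)
    fine = np.linspace(0.0, n_frames - 1, n_frames * factor)
    return FrontProfile(raw=fn(frames), smoothed=fn(frames), resampled=fn(fine),
                        factor=factor)
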