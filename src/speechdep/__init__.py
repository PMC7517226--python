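"""speechdep: speech-based depression screening with ensembles of 1-D CNNs.

The pipeline turns long per-speaker interview recordings into balanced sets
of 4-s log-spectrogram samples, trains M identically configured but
differently initialized frequency-spanning convolutional classifiers, fuses
their per-sample probabilities into a speaker-level decision, and evaluates
per-class F1 at speaker level.  A synthetic-corpus generator with a tunable
class signature makes every stage testable without access-restricted
clinical data.
"""

from .corpus import (
    AudioRecording,
    EmptyRecordingError,
    FormatError,
    SegmentAnnotation,
    SpeakerRecord,
    ValidationError,
    binarize_phq8,
    load_participant_audio,
    load_roster,
    save_roster,
)
from .synth import SynthConfig, generate_corpus, generate_speaker_audio, synthesize_roster
from .sampler import (
    CropSpec,
    InfeasibleSamplingError,
    SamplingPlan,
    count_available_crops,
    crop_test_speakers,
    materialize_plan,
    optimize_sampling_plan,
)
from .features import (
    LogSpectrogram,
    StftParams,
    compute_log_spectrogram,
    extract_crop_features,
    minmax_normalize,
)
from .cnn import (
    CnnConfig,
    DivergenceError,
    OneDCnn,
    build_model,
    pooled_length,
    predict_samples,
    train_model,
)
from .aggregation import (
    labels_from_probs,
    speaker_label_mean_prob,
    speaker_label_mode,
    tie_coin,
)
from .ensemble import (
    EnsembleConfig,
    f1_vs_m_curve,
    fuse,
    fuse_method1,
    fuse_method2,
    fuse_method3,
    predict_table,
    train_ensemble,
)
from .evaluation import (
    ClassMetrics,
    crossval_evaluate,
    f1_from_pr,
    per_class_metrics,
    relative_improvement,
    speaker_kfold_split,
)

__version__ = "0.1.0"
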