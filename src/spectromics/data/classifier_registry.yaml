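# The 30-entry classifier roster benchmarked on the selected features.
# Edit freely: each entry names a scikit-learn estimator and its
# constructor arguments (defaults unless noted).  Estimators that require
# non-negative inputs are wrapped in a MinMax scaling pipeline.
entries:
  - {name: LogisticRegression,           cls: sklearn.linear_model.LogisticRegression, params: {max_iter: 2000}}
  - {name: RidgeClassifier,              cls: sklearn.linear_model.RidgeClassifier, params: {}}
  - {name: SGDClassifier,                cls: sklearn.linear_model.SGDClassifier, params: {loss: log_loss}}
  - {name: Perceptron,                   cls: sklearn.linear_model.Perceptron, params: {}}
  - {name: PassiveAggressiveClassifier,  cls: sklearn.linear_model.SGDClassifier, params: {loss: hinge, penalty: null, learning_rate: pa1, eta0: 1.0}}
  - {name: LinearSVC,                    cls: sklearn.svm.LinearSVC, params: {max_iter: 5000}}
  - {name: SVC,                          cls: sklearn.svm.SVC, params: {probability: true}}
  - {name: SVCPoly,                      cls: sklearn.svm.SVC, params: {kernel: poly, probability: true}}
  - {name: SVCSigmoid,                   cls: sklearn.svm.SVC, params: {kernel: sigmoid, probability: true}}
  - {name: NuSVC,                        cls: sklearn.svm.NuSVC, params: {probability: true}}
  - {name: KNeighborsClassifier,         cls: sklearn.neighbors.KNeighborsClassifier, params: {}}
  - {name: NearestCentroid,              cls: sklearn.neighbors.NearestCentroid, params: {}}
  - {name: GaussianProcessClassifier,    cls: sklearn.gaussian_process.GaussianProcessClassifier, params: {}}
  - {name: DecisionTreeClassifier,       cls: sklearn.tree.DecisionTreeClassifier, params: {}}
  - {name: ExtraTreeClassifier,          cls: sklearn.tree.ExtraTreeClassifier, params: {}}
  - {name: RandomForestClassifier,       cls: sklearn.ensemble.RandomForestClassifier, params: {}}
  - {name: ExtraTreesClassifier,         cls: sklearn.ensemble.ExtraTreesClassifier, params: {}}
  - {name: GradientBoostingClassifier,   cls: sklearn.ensemble.GradientBoostingClassifier, params: {}}
  - {name: HistGradientBoostingClassifier, cls: sklearn.ensemble.HistGradientBoostingClassifier, params: {}}
  - {name: AdaBoostClassifier,           cls: sklearn.ensemble.AdaBoostClassifier, params: {}}
  - {name: BaggingClassifier,            cls: sklearn.ensemble.BaggingClassifier, params: {}}
  - {name: GaussianNB,                   cls: sklearn.naive_bayes.GaussianNB, params: {}}
  - {name: BernoulliNB,                  cls: sklearn.naive_bayes.BernoulliNB, params: {}}
  - {name: MultinomialNB,                cls: sklearn.naive_bayes.MultinomialNB, params: {}, scale: minmax}
  - {name: ComplementNB,                 cls: sklearn.naive_bayes.ComplementNB, params: {}, scale: minmax}
  - {name: LinearDiscriminantAnalysis,   cls: sklearn.discriminant_analysis.LinearDiscriminantAnalysis, params: {}}
  - {name: QuadraticDiscriminantAnalysis, cls: sklearn.discriminant_analysis.QuadraticDiscriminantAnalysis, params: {}}
  - {name: MLPClassifier,                cls: sklearn.neural_network.MLPClassifier, params: {max_iter: 1000}}
  - {name: LabelSpreading,               cls: sklearn.semi_supervised.LabelSpreading, params: {}}
  - {name: DummyClassifier,              cls: sklearn.dummy.DummyClassifier, params: {}}
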