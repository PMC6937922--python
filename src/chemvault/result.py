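"""Explicit error channel for fallible operations.

Operations that can fail return a :class:`Result` carrying either a value
or a structured error, instead of raising through the public surface.
This keeps every failure mode visible in the signature and forces callers
to handle it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Generic, TypeVar

T = TypeVar("T")
U = TypeVar("U")
E = TypeVar("E")


@dataclass(frozen=True)
class Result(Generic[T, E]):
    """Either a success value or an error, never both."""

    _value: T | None = None
    _error: E | None = None

    @staticmethod
    def ok(value: T) -> "Result[T, E]":
        return Result(_value=value)

    @staticmethod
    def err(error: E) -> "Result[T, E]":
        if error is None:
            raise ValueError("error payload must not be None")
        return Result(_error=error)

    @property
    def is_ok(self) -> bool:
        return self._error is None

    @property
    def is_err(self) -> bool:
        return self._error is not None

    @property
    def value(self) -> T:
        if self._error is not None:
            raise RuntimeError(f"unwrapped error result: {self._error!r}")
        return self._value  # type: ignore[return-value]

    @property
    def error(self) -> E:
        if self._error is None:
            raise RuntimeError("unwrapped value result as error")
        return self._error

    def map(self, f: Callable[[T], U]) -> "Result[U, E]":
        if self.is_err:
            return Result(_error=self._error)  # type: ignore[arg-type]
        return Result.ok(f(self.value))

    def and_then(self, f: "Callable[[T], Result[U, E]]") -> "Result[U, E]":
        if self.is_err:
            return Result(_error=self._error)  # type: ignore[arg-type]
        return f(self.value)
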